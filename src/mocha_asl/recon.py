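"""Reconstruction solvers and baselines.

``mocha_reconstruct`` minimizes the convex quadratic

    f(x) = w/(2 Np) sum_i ||E T_i B x - d_i||^2 + beta R(x)

where the data-fidelity weight ``w`` defaults to the number of k-space
samples (unnormalized-DFT energy convention, in which the reference
regularization weight beta = 20 was calibrated), by steepest descent with
exact line search (alpha = g'g / g'Hg, the Hessian
applied matrix-free through the forward/adjoint operators and the prior
Hessian).  Exact line search on a convex quadratic makes the objective trace
monotone non-increasing and converges to the global minimizer from any start.

``reconstruct_m0`` is the single-volume special case used for the calibration
scan.  The baselines are the standard zero-filled inverse-FFT reconstruction
with coil combination and motion correction, RSS-ratio coil-map estimation
and Lucy-Richardson deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

from .forward_model import (
    AcquisitionModel,
    PSFModel,
    RigidTransform,
    apply_rigid,
    ifft3c,
)
from .prior import PriorSpec, prior_gradient

__all__ = [
    "SolveReport",
    "mocha_reconstruct",
    "reconstruct_m0",
    "estimate_coil_maps",
    "coil_combine",
    "standard_reconstruct",
    "lucy_richardson",
]


@dataclass
class SolveReport:
    """Objective and step-size trace of one solver run."""

    objective: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)
    iterations_run: int = 0
    stagnated: bool = False


def _check_finite(arrs, what):
    for a in arrs:
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite values in {what}")


def mocha_reconstruct(
    pairs,
    model: AcquisitionModel,
    spec: PriorSpec | None,
    iters: int = 100,
    tol: float | None = None,
    refresh_every: int = 20,
    data_weight: float | None = None,
) -> tuple[np.ndarray, SolveReport]:
    """Model-based reconstruction of the perfusion-weighted image.

    Parameters
    ----------
    pairs
        Control-minus-label multi-coil k-space volumes, one per pair,
        each of shape ``(L, *shape_low)``.
    model
        Acquisition model whose ``transforms`` match the pairs.
    spec
        Prior specification; ``None`` or ``beta == 0`` disables regularization.
    iters
        Number of steepest-descent iterations (100 by default).
    tol
        Optional early stop on the relative gradient norm (off by default).
    refresh_every
        Recompute the gradient and residuals from scratch every this many
        iterations to keep the cheap recurrences drift-free.
    data_weight
        Weight of the data-fidelity term.  Defaults to the number of low-res
        k-space samples, i.e. the squared norm is counted in unnormalized-DFT
        units; the default beta = 20 is calibrated in this convention.
    """
    pairs = [np.asarray(d) for d in pairs]
    if len(pairs) != model.num_pairs:
        raise ValueError("number of data volumes must match the model's motion states")
    _check_finite(pairs, "k-space data")
    n_pairs = len(pairs)
    beta = 0.0 if spec is None else float(spec.beta)
    if data_weight is None:
        # Data fidelity counted in unnormalized-DFT energy (one unit per k-space
        # sample), the convention the reference beta values are calibrated in;
        # the operators themselves stay unitary.
        data_weight = float(np.prod(model.shape_low))
    scale = data_weight / n_pairs

    def h_apply(p):
        out = np.zeros(model.shape_high, dtype=complex)
        for i in range(n_pairs):
            out += model.adjoint_pair(model.forward_pair(p, i), i)
        out *= scale
        if beta > 0:
            out += beta * prior_gradient(p, spec)
        return out

    b = np.zeros(model.shape_high, dtype=complex)
    for i, d in enumerate(pairs):
        b += model.adjoint_pair(d, i)
    b *= scale
    c0 = sum(float(np.vdot(d, d).real) for d in pairs) * scale / 2.0

    x = np.zeros(model.shape_high, dtype=complex)
    g = -b  # gradient of f at x = 0
    report = SolveReport(objective=[c0])
    g0_norm = np.linalg.norm(g)
    for k in range(iters):
        gg = float(np.vdot(g, g).real)
        if gg == 0.0:
            break
        if tol is not None and np.sqrt(gg) <= tol * g0_norm:
            break
        hg = h_apply(g)
        curvature = float(np.vdot(g, hg).real)
        if curvature <= 0:
            report.stagnated = True
            warnings.warn("zero curvature along the gradient; solver stagnated")
            break
        alpha = gg / curvature
        x = x - alpha * g
        if (k + 1) % refresh_every == 0:
            g = h_apply(x) - b
        else:
            g = g - alpha * hg
        # f(x) = 0.5 Re<x, Hx> - Re<b, x> + c0, with Hx = g + b
        obj = 0.5 * float(np.vdot(x, g).real) - 0.5 * float(np.vdot(b, x).real) + c0
        report.step_sizes.append(alpha)
        report.objective.append(obj)
        report.iterations_run = k + 1
    return x, report


def reconstruct_m0(
    s: np.ndarray,
    model: AcquisitionModel,
    spec: PriorSpec | None,
    iters: int = 100,
    **kwargs,
) -> tuple[np.ndarray, SolveReport]:
    """Reconstruct the M0 calibration volume (single k-space, identity motion)."""
    if model.num_pairs != 1:
        model = model.single_state()
    return mocha_reconstruct([s], model, spec, iters=iters, **kwargs)


def estimate_coil_maps(coil_images: np.ndarray, eps_frac: float = 1e-6) -> np.ndarray:
    """Coil sensitivities as each coil image over the root sum of squares.

    Where the RSS is below ``eps_frac`` times its maximum, the maps are zero.
    """
    coil_images = np.asarray(coil_images)
    rss = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))
    top = rss.max()
    if top == 0:
        warnings.warn("all-zero coil images; returning zero maps")
        return np.zeros_like(coil_images)
    good = rss > eps_frac * top
    maps = np.zeros_like(coil_images, dtype=complex)
    maps[:, good] = coil_images[:, good] / rss[good]
    return maps


def coil_combine(images: np.ndarray, maps: np.ndarray, eps_frac: float = 1e-6) -> np.ndarray:
    """Conjugate-map weighted sum normalized by RSS^2 (plain IFFT for one uniform coil)."""
    num = np.sum(np.conj(maps) * images, axis=0)
    den = np.sum(np.abs(maps) ** 2, axis=0)
    out = np.zeros_like(num)
    good = den > eps_frac * max(den.max(), np.finfo(float).tiny)
    out[good] = num[good] / den[good]
    return out


def standard_reconstruct(
    controls,
    labels,
    transforms: list[RigidTransform],
    maps: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Direct inverse-FFT reconstruction of the perfusion-weighted image.

    Per image: zero-filled inverse FFT per coil, coil combination, rigid
    motion correction (resampling along the inverse transform); then pairwise
    control-label subtraction and averaging.
    """
    if len(controls) != len(labels) or len(controls) != len(transforms):
        raise ValueError("controls, labels and transforms must have equal length")
    acc = None
    for kc, kl, t in zip(controls, labels, transforms):
        ic = coil_combine(ifft3c(np.asarray(kc)), maps)
        il = coil_combine(ifft3c(np.asarray(kl)), maps)
        if not t.is_identity:
            ic = apply_rigid(ic, t, spacing, inverse=True)
            il = apply_rigid(il, t, spacing, inverse=True)
        diff = ic - il
        acc = diff if acc is None else acc + diff
    return acc / len(controls)


def lucy_richardson(
    img: np.ndarray,
    psf: PSFModel,
    iters: int = 100,
    boundary: str = "wrap",
    eps: float = 1e-12,
    u0: np.ndarray | None = None,
) -> np.ndarray:
    """Lucy-Richardson deconvolution with a separable nonnegative kernel.

    Multiplicative update u <- u * K'(img / (K u)); with a unit-sum kernel and
    periodic (``wrap``) boundary handling the total intensity is conserved.
    """
    img = np.asarray(img, dtype=float)
    if np.any(img < 0):
        raise ValueError("Lucy-Richardson requires a nonnegative image (use the magnitude)")
    kernels = psf.kernels()

    def k_apply(u):
        out = u
        for axis, kernel in enumerate(kernels):
            if np.isclose(kernel[kernel.size // 2], 1.0):
                continue
            out = convolve1d(out, kernel, axis=axis, mode=boundary)
        return out

    u = img.copy() if u0 is None else np.asarray(u0, dtype=float).copy()
    for _ in range(iters):
        denom = k_apply(u)
        ratio = img / np.maximum(denom, eps)
        u = u * k_apply(ratio)  # symmetric kernel: K' = K
    return u
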