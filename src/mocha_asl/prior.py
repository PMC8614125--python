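"""Anatomically weighted quadratic penalty with Gaussian similarity coefficients.

R(x) = sum_j sum_{b in N_j} omega_jb xi_jb |x_j - x_b|^2

where omega_jb is a Gaussian similarity of the (normalized) anatomical image
intensities of voxels j and b, and xi_jb is an inverse-Euclidean-distance
proximity coefficient normalized so the nearest neighbor has xi = 1.  Each
ordered pair is counted once, so every undirected edge contributes twice.
For complex images the penalty acts on real and imaginary parts independently
(complex modulus), keeping R real and convex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PriorSpec",
    "neighborhood_offsets",
    "similarity_weights",
    "proximity_coeffs",
    "normalize_anatomy",
    "build_prior",
    "prior_value",
    "prior_gradient",
]


def neighborhood_offsets(size=(3, 3, 3)) -> np.ndarray:
    """Integer voxel offsets of a box neighborhood, excluding (0,0,0)."""
    size = tuple(int(s) for s in size)
    if any(s < 1 or s % 2 == 0 for s in size):
        raise ValueError("neighborhood size must be odd and >= 1 per axis")
    half = [s // 2 for s in size]
    offs = [
        (i, j, k)
        for i in range(-half[0], half[0] + 1)
        for j in range(-half[1], half[1] + 1)
        for k in range(-half[2], half[2] + 1)
        if (i, j, k) != (0, 0, 0)
    ]
    return np.array(offs, dtype=int)


def proximity_coeffs(offsets: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """xi = 1 / Euclidean distance (mm), normalized so the maximum is 1."""
    offsets = np.asarray(offsets)
    if np.any(np.all(offsets == 0, axis=1)):
        raise ValueError("offsets must exclude the zero offset")
    d = np.linalg.norm(offsets * np.asarray(spacing, dtype=float), axis=1)
    xi = 1.0 / d
    return xi / xi.max()


def normalize_anatomy(v: np.ndarray, percentile: float = 99.5) -> np.ndarray:
    """Rescale the anatomical image to [0, 1] by its upper percentile."""
    v = np.asarray(v, dtype=float)
    top = np.percentile(v, percentile)
    if top <= 0:
        raise ValueError("anatomical image has non-positive intensity scale")
    return np.clip(v / top, 0.0, 1.0)


def _offset_slices(shape, off):
    """Slices (src, nbr) such that x[nbr][j] = x[j + off] for valid j = x[src]."""
    src, nbr = [], []
    for n, o in zip(shape, off):
        a, b = max(0, -o), n - max(0, o)
        src.append(slice(a, b))
        nbr.append(slice(a + o, b + o))
    return tuple(src), tuple(nbr)


def similarity_weights(v: np.ndarray, sigma: float, offsets: np.ndarray) -> np.ndarray:
    """Gaussian similarity omega_jb = exp(-(v_j-v_b)^2 / 2 sigma^2) / (sqrt(2 pi) sigma).

    Returns an array of shape (n_offsets, *v.shape); entries whose neighbor
    falls outside the grid are zero.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = np.asarray(v, dtype=float)
    const = 1.0 / (np.sqrt(2.0 * np.pi) * sigma)
    omega = np.zeros((len(offsets),) + v.shape)
    for k, off in enumerate(offsets):
        src, nbr = _offset_slices(v.shape, off)
        diff = v[src] - v[nbr]
        omega[k][src] = const * np.exp(-(diff**2) / (2.0 * sigma**2))
    return omega


@dataclass
class PriorSpec:
    """Frozen prior configuration: offsets, weights and hyperparameters."""

    offsets: np.ndarray
    omega: np.ndarray  # (K, *grid), zero where the neighbor is out of bounds
    xi: np.ndarray  # (K,)
    beta: float = 20.0
    sigma: float = 0.15

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if np.any(self.omega < 0):
            raise ValueError("similarity weights must be nonnegative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.omega.shape[1:]


def build_prior(
    anatomy: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    beta: float = 20.0,
    sigma: float = 0.15,
    neighborhood=(3, 3, 3),
    normalize: bool = True,
) -> PriorSpec:
    """Precompute the prior weights from the anatomical image (weights are frozen)."""
    offs = neighborhood_offsets(neighborhood)
    v = normalize_anatomy(anatomy) if normalize else np.asarray(anatomy, dtype=float)
    return PriorSpec(
        offsets=offs,
        omega=similarity_weights(v, sigma, offs),
        xi=proximity_coeffs(offs, spacing),
        beta=beta,
        sigma=sigma,
    )


def prior_value(x: np.ndarray, spec: PriorSpec) -> float:
    """R(x), the double sum over ordered voxel pairs."""
    if x.shape != spec.shape:
        raise ValueError(f"expected image of shape {spec.shape}, got {x.shape}")
    total = 0.0
    for k, off in enumerate(spec.offsets):
        src, nbr = _offset_slices(x.shape, off)
        diff = x[src] - x[nbr]
        total += spec.xi[k] * float(np.sum(spec.omega[k][src] * np.abs(diff) ** 2))
    return total


def prior_gradient(x: np.ndarray, spec: PriorSpec) -> np.ndarray:
    """Gradient of R: dR/dx_j = 2 sum_b (w_jb + w_bj)(x_j - x_b), w = omega * xi.

    Linear in x; applying it to a direction vector gives the prior Hessian
    action used by the exact line search.
    """
    if x.shape != spec.shape:
        raise ValueError(f"expected image of shape {spec.shape}, got {x.shape}")
    g = np.zeros_like(x, dtype=np.result_type(x.dtype, float))
    for k, off in enumerate(spec.offsets):
        src, nbr = _offset_slices(x.shape, off)
        wd = (2.0 * spec.xi[k]) * spec.omega[k][src] * (x[src] - x[nbr])
        g[src] += wd
        g[nbr] -= wd
    return g
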