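"""CBF quantification, partial-volume correction, error metrics and PSF estimation.

Quantification follows the single-PLD pCASL consensus model:

    CBF = 6000 * lambda * xP * exp(PLD / T1b)
          ------------------------------------------   [mL/100 g/min]
          2 * alpha * T1b[s] * xM0 * (1 - exp(-tau / T1b))

with the label duration tau, post-label delay PLD and T1 of blood given in
milliseconds (the exponent ratios are unitless; the multiplicative T1b is
converted to seconds, which the 6000 s->min/100g factor assumes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate
from scipy.optimize import minimize_scalar

from .forward_model import build_lorentzian_kernel

__all__ = [
    "QuantConstants",
    "PVMaps",
    "ROILabelMap",
    "cbf_scale",
    "quantify_cbf",
    "invert_cbf_to_label",
    "pvc_3dlr",
    "nrmse",
    "roi_stats",
    "estimate_psf_fwhm",
]


@dataclass(frozen=True)
class QuantConstants:
    """pCASL quantification constants (times in ms)."""

    lambda_bp: float = 0.9  # brain-blood partition coefficient, mL/g
    tau: float = 1500.0  # label duration
    pld: float = 1800.0  # post-label delay
    t1_blood: float = 1650.0  # T1 of arterial blood at 3T
    alpha_eff: float = 0.85  # labeling efficiency

    def __post_init__(self):
        vals = (self.lambda_bp, self.tau, self.pld, self.t1_blood, self.alpha_eff)
        if any(v <= 0 for v in vals):
            raise ValueError("quantification constants must be strictly positive")
        if self.alpha_eff > 1:
            raise ValueError("labeling efficiency cannot exceed 1")


@dataclass
class PVMaps:
    """Gray/white/CSF partial-volume fractions on a common grid."""

    pgm: np.ndarray
    pwm: np.ndarray
    pcsf: np.ndarray

    def __post_init__(self):
        for p in (self.pgm, self.pwm, self.pcsf):
            if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
                raise ValueError("partial-volume fractions must lie in [0, 1]")
        if np.any(self.pgm + self.pwm + self.pcsf > 1 + 1e-6):
            raise ValueError("partial-volume fractions must sum to at most 1")


@dataclass
class ROILabelMap:
    """Integer label volume with a name table; 0 is background."""

    labels: np.ndarray
    names: dict[int, str]

    def mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.names.items() if v == name]
        if not ids:
            raise KeyError(f"no ROI named {name!r}")
        return np.isin(self.labels, ids)


def cbf_scale(k: QuantConstants = QuantConstants()) -> float:
    """Scale factor S such that CBF = S * xP / xM0 (mL/100 g/min)."""
    num = 6000.0 * k.lambda_bp * np.exp(k.pld / k.t1_blood)
    den = 2.0 * k.alpha_eff * (k.t1_blood / 1000.0) * (1.0 - np.exp(-k.tau / k.t1_blood))
    return num / den


def quantify_cbf(
    xp: np.ndarray,
    xm0: np.ndarray,
    k: QuantConstants = QuantConstants(),
    m0_threshold_frac: float = 0.1,
) -> np.ndarray:
    """Voxelwise CBF; masked to 0 where xM0 is below a fraction of its robust maximum."""
    xp = np.asarray(xp, dtype=float)
    xm0 = np.asarray(xm0, dtype=float)
    if not (np.all(np.isfinite(xp)) and np.all(np.isfinite(xm0))):
        raise ValueError("non-finite inputs to CBF quantification")
    thresh = m0_threshold_frac * np.percentile(xm0, 99.0)
    good = xm0 > max(thresh, 0.0)
    out = np.zeros_like(xp)
    out[good] = cbf_scale(k) * xp[good] / xm0[good]
    return out


def invert_cbf_to_label(
    cbf: np.ndarray,
    xm0: np.ndarray,
    control: np.ndarray,
    k: QuantConstants = QuantConstants(),
) -> np.ndarray:
    """Label image such that control - label round-trips through ``quantify_cbf``."""
    cbf = np.asarray(cbf, dtype=float)
    if not np.all(np.isfinite(cbf)):
        raise ValueError("non-finite CBF input")
    xp = cbf * np.asarray(xm0, dtype=float) / cbf_scale(k)
    return np.asarray(control, dtype=float) - xp


def pvc_3dlr(
    ratio: np.ndarray,
    pv: PVMaps,
    kernel=(5, 5, 5),
    min_pv: float = 0.05,
    max_cond: float = 1e6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """3D linear-regression partial-volume correction on the xP/xM0 ratio.

    Per voxel, least squares over the local kernel K of
    ``r_k ~ pGM_k * fGM + pWM_k * fWM``.  The two-parameter fit is used where
    the 2x2 normal matrix has condition number below ``max_cond``; elsewhere a
    single-tissue fit is used.  A tissue map is NaN wherever the voxel's own
    PV fraction is at most ``min_pv`` (no local support for that tissue).

    Returns ``(fgm, fwm, combined)`` in ratio units, where
    ``combined = pGM * fGM + pWM * fWM`` (NaNs treated as 0 contribution).
    """
    kernel = tuple(int(s) for s in kernel)
    if any(s < 1 or s % 2 == 0 for s in kernel):
        raise ValueError("kernel dimensions must be odd")
    r = np.asarray(ratio, dtype=float)
    g, w = np.asarray(pv.pgm, dtype=float), np.asarray(pv.pwm, dtype=float)
    ones = np.ones(kernel)

    def box(a):  # clipped kernel sums (out-of-volume voxels contribute nothing)
        return correlate(a, ones, mode="constant", cval=0.0)

    sgg, sgw, sww = box(g * g), box(g * w), box(w * w)
    sgr, swr = box(g * r), box(w * r)

    det = sgg * sww - sgw**2
    tr = sgg + sww
    disc = np.sqrt(np.maximum((sgg - sww) ** 2 + 4 * sgw**2, 0.0))
    lam_max = (tr + disc) / 2
    lam_min = (tr - disc) / 2
    full_rank = (lam_min > 0) & (lam_max < max_cond * np.maximum(lam_min, 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        fgm2 = (sww * sgr - sgw * swr) / det
        fwm2 = (sgg * swr - sgw * sgr) / det
        fgm1 = np.where(sgg > 0, sgr / np.where(sgg > 0, sgg, 1.0), np.nan)
        fwm1 = np.where(sww > 0, swr / np.where(sww > 0, sww, 1.0), np.nan)

    fgm = np.where(full_rank, fgm2, fgm1)
    fwm = np.where(full_rank, fwm2, fwm1)
    fgm[g <= min_pv] = np.nan
    fwm[w <= min_pv] = np.nan

    combined = np.where(np.isnan(fgm), 0.0, g * np.nan_to_num(fgm)) + np.where(
        np.isnan(fwm), 0.0, w * np.nan_to_num(fwm)
    )
    return fgm, fwm, combined


def nrmse(x: np.ndarray, x_gt: np.ndarray, roi: np.ndarray | None = None) -> float:
    """Normalized RMS error in percent: 100 * sqrt(sum (x-gt)^2 / sum gt^2) over the ROI."""
    x = np.asarray(x, dtype=float)
    x_gt = np.asarray(x_gt, dtype=float)
    if roi is not None:
        x, x_gt = x[roi], x_gt[roi]
    denom = float(np.sum(x_gt**2))
    if denom == 0:
        raise ValueError("NRMSE undefined: ground truth is all zero on the ROI")
    return 100.0 * float(np.sqrt(np.sum((x - x_gt) ** 2) / denom))


def roi_stats(
    cbf: np.ndarray,
    rois: ROILabelMap,
    ground_truth: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region voxel count, mean and SD (and NRMSE against an optional truth)."""
    rows = []
    for label, name in sorted(rois.names.items()):
        m = rois.labels == label
        n = int(m.sum())
        if n == 0:
            warnings.warn(f"ROI {name!r} is empty; omitted")
            continue
        row = {
            "region": name,
            "n_voxels": n,
            "mean": float(np.mean(cbf[m])),
            "sd": float(np.std(cbf[m])),
        }
        if ground_truth is not None:
            row["nrmse_pct"] = nrmse(cbf, ground_truth, m)
            gt_mean = float(np.mean(ground_truth[m]))
            row["gt_mean"] = gt_mean
            if gt_mean != 0:
                row["bias_pct"] = 100.0 * (row["mean"] - gt_mean) / gt_mean
        rows.append(row)
    return pd.DataFrame(rows)


def _lorentzian_autocorr(fwhm: float, max_lag: int, radius: int = 32) -> np.ndarray:
    """Normalized discrete autocorrelation of a sampled Lorentzian kernel."""
    k = build_lorentzian_kernel(fwhm, radius)
    full = np.correlate(k, k, mode="full")
    mid = full.size // 2
    ac = full[mid : mid + max_lag + 1]
    return ac / ac[0]


def estimate_psf_fwhm(
    cl_differences,
    axis: int = 2,
    max_lag: int = 10,
    fwhm_bounds=(1e-3, 10.0),
) -> float:
    """Estimate the through-plane PSF FWHM (voxels) from repeated C-L differences.

    The repeated difference volumes are mean-subtracted per voxel to isolate
    noise residuals, whose spatial correlation along the superior-inferior
    axis reflects the blur.  The 1D autocorrelation along that axis is
    averaged over measurements and both in-plane axes, normalized at lag 0
    and fitted with the autocorrelation of a sampled Lorentzian kernel.
    """
    arr = np.stack([np.asarray(d, dtype=float) for d in cl_differences], axis=0)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 difference volumes")
    res = arr - arr.mean(axis=0, keepdims=True)
    res = np.moveaxis(res, axis + 1, -1)  # (M, a, b, z)
    nz = res.shape[-1]
    max_lag = min(max_lag, nz - 1)
    cols = res.reshape(-1, nz)
    # autocorrelation via zero-padded FFT, summed over all columns
    nfft = 2 * nz
    spec = np.fft.rfft(cols, n=nfft, axis=1)
    ac_full = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : max_lag + 1]
    ac = ac_full.sum(axis=0)
    if not np.isfinite(ac).all() or ac[0] <= 0:
        raise ValueError("degenerate residuals: autocorrelation fit failed")
    ac = ac / ac[0]

    def loss(fwhm):
        return float(np.sum((ac - _lorentzian_autocorr(fwhm, max_lag)) ** 2))

    result = minimize_scalar(loss, bounds=fwhm_bounds, method="bounded")
    return float(result.x)
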