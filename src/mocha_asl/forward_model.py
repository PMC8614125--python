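"""Linear operators of the ASL acquisition forward model and their exact adjoints.

The model maps a high-resolution perfusion-weighted image ``x`` to the
multi-coil k-space data of one control-label pair:

    d_i = (I_L (x) Phi F) C D M_i B x

with ``B`` a separable Lorentzian point-spread-function blur on the high-res
grid, ``M_i`` the rigid transform to the i-th motion state, ``D`` a
block-average downsampling to the acquisition grid, ``C`` coil-sensitivity
modulation, ``F`` the unitary centered 3D DFT and ``Phi`` a Cartesian
undersampling mask.  B0 distortion and the noise-covariance weighting are
identity.  Every operator exposes an adjoint that satisfies the dot-product
identity to round-off, which the gradient of the reconstruction objective
relies on.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import convolve1d

__all__ = [
    "RigidTransform",
    "PSFModel",
    "SamplingMask",
    "AcquisitionModel",
    "build_lorentzian_kernel",
    "apply_blur",
    "apply_rigid",
    "downsample",
    "fft3c",
    "ifft3c",
    "make_undersampling_mask",
    "forward_pair",
    "adjoint_pair",
]


# ---------------------------------------------------------------------------
# Rigid transforms


def _rotation_matrix(rot_deg) -> np.ndarray:
    """Rotation matrix R = Rz @ Ry @ Rx for angles in degrees."""
    ax, ay, az = np.deg2rad(np.asarray(rot_deg, dtype=float))
    ca, sa = np.cos(ax), np.sin(ax)
    cb, sb = np.cos(ay), np.sin(ay)
    cc, sc = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _euler_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """Angles (deg) such that ``_rotation_matrix`` reproduces ``r`` (zyx order)."""
    ay = np.arctan2(-r[2, 0], np.hypot(r[0, 0], r[1, 0]))
    ax = np.arctan2(r[2, 1], r[2, 2])
    az = np.arctan2(r[1, 0], r[0, 0])
    return tuple(np.rad2deg([ax, ay, az]))


@dataclass(frozen=True)
class RigidTransform:
    """Rigid body motion: rotations (deg) about the grid center, translations (mm)."""

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        return _rotation_matrix(self.rotations_deg), np.asarray(
            self.translations_mm, dtype=float
        )

    def inverse(self) -> "RigidTransform":
        r, t = self.matrix()
        rinv = r.T
        tinv = -rinv @ t
        return RigidTransform(_euler_from_matrix(rinv), tuple(tinv))

    @property
    def is_identity(self) -> bool:
        return not (any(self.rotations_deg) or any(self.translations_mm))

    def to_dict(self) -> dict:
        return {
            "rot_deg": list(map(float, self.rotations_deg)),
            "trans_mm": list(map(float, self.translations_mm)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["rot_deg"]), tuple(d["trans_mm"]))


@functools.lru_cache(maxsize=64)
def _interp_matrix(shape, spacing, a_flat, t):
    """Sparse trilinear interpolation matrix sampling x at ``A p + t`` (mm, about center)."""
    shape = np.asarray(shape)
    spacing_arr = np.asarray(spacing, dtype=float)
    a = np.asarray(a_flat, dtype=float).reshape(3, 3)
    tvec = np.asarray(t, dtype=float)
    n = int(np.prod(shape))
    center = (shape - 1) / 2.0 * spacing_arr

    idx = np.indices(shape).reshape(3, -1).astype(float)
    world = idx * spacing_arr[:, None] - center[:, None]
    src = a @ world + tvec[:, None]
    f = (src + center[:, None]) / spacing_arr[:, None]
    f0 = np.floor(f).astype(np.int64)
    w = f - f0

    rows_all, cols_all, data_all = [], [], []
    base_rows = np.arange(n, dtype=np.int64)
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        ci = f0 + off[:, None]
        weight = np.ones(n)
        for ax in range(3):
            weight *= w[ax] if off[ax] else (1.0 - w[ax])
        valid = np.all((ci >= 0) & (ci < shape[:, None]), axis=0) & (weight > 0)
        cols = np.ravel_multi_index(tuple(ci[:, valid]), tuple(shape))
        rows_all.append(base_rows[valid])
        cols_all.append(cols)
        data_all.append(weight[valid])
    mat = sp.csr_matrix(
        (np.concatenate(data_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n, n),
    )
    mat.sum_duplicates()
    return mat


def rigid_interp_matrix(shape, spacing, transform: RigidTransform, inverse: bool = False):
    """Interpolation matrix for resampling under a rigid transform.

    The forward map moves the object by ``transform``; the matrix therefore
    pulls values from the inverse-transformed coordinates.  With
    ``inverse=True`` the resampling applies the inverse motion instead.
    """
    r, t = transform.matrix()
    if inverse:
        a, tv = r, t  # sample at T p  -> applies T^{-1} to the image
    else:
        a, tv = r.T, -(r.T @ t)  # sample at T^{-1} p -> applies T
    return _interp_matrix(
        tuple(int(s) for s in shape),
        tuple(float(s) for s in spacing),
        tuple(a.ravel()),
        tuple(tv),
    )


def apply_rigid(
    x: np.ndarray,
    transform: RigidTransform,
    spacing=(1.0, 1.0, 1.0),
    inverse: bool = False,
    adjoint: bool = False,
) -> np.ndarray:
    """Resample ``x`` under a rigid motion with trilinear interpolation.

    The adjoint is the transpose of the interpolation matrix (not resampling
    along the inverse transform), so the dot-product identity holds exactly.
    """
    if transform.is_identity:
        return x.copy()
    mat = rigid_interp_matrix(x.shape, spacing, transform, inverse=inverse)
    vec = x.ravel()
    out = (mat.T @ vec) if adjoint else (mat @ vec)
    return out.reshape(x.shape)


# ---------------------------------------------------------------------------
# PSF blurring


def build_lorentzian_kernel(fwhm_voxels: float, truncation_radius: int = 8) -> np.ndarray:
    """1D Lorentzian profile 1/(1+(2z/FWHM)^2) at integer offsets, unit sum.

    ``fwhm_voxels == 0`` gives a delta kernel.
    """
    if fwhm_voxels < 0:
        raise ValueError("FWHM must be nonnegative")
    if truncation_radius < 1:
        raise ValueError("truncation_radius must be >= 1")
    z = np.arange(-truncation_radius, truncation_radius + 1, dtype=float)
    if fwhm_voxels == 0:
        k = (z == 0).astype(float)
    else:
        k = 1.0 / (1.0 + (2.0 * z / fwhm_voxels) ** 2)
    return k / k.sum()


@dataclass(frozen=True)
class PSFModel:
    """Separable point-spread function; per-axis FWHM in voxels of its grid."""

    fwhm_voxels: tuple[float, float, float]
    truncation_radius: int = 8
    kind: str = "lorentzian"

    def kernels(self) -> list[np.ndarray]:
        if self.kind != "lorentzian":
            raise ValueError(f"unknown PSF kind {self.kind!r}")
        return [
            build_lorentzian_kernel(f, self.truncation_radius) for f in self.fwhm_voxels
        ]

    @property
    def is_delta(self) -> bool:
        return all(f == 0 for f in self.fwhm_voxels)


def _convolve1d_complex(x, kernel, axis):
    if np.iscomplexobj(x):
        return convolve1d(x.real, kernel, axis=axis, mode="constant") + 1j * convolve1d(
            x.imag, kernel, axis=axis, mode="constant"
        )
    return convolve1d(x, kernel, axis=axis, mode="constant")


def apply_blur(x: np.ndarray, psf: PSFModel, adjoint: bool = False) -> np.ndarray:
    """Separable convolution with zero-padded boundaries.

    Kernels are symmetric, so the adjoint equals the forward operator; the
    flag is accepted for interface symmetry.
    """
    del adjoint  # symmetric real kernel: B' = B
    out = x
    for axis, kernel in enumerate(psf.kernels()):
        if kernel.size == 1 or np.isclose(kernel[kernel.size // 2], 1.0):
            continue
        out = _convolve1d_complex(out, kernel, axis)
    return np.array(out, copy=True) if out is x else out


# ---------------------------------------------------------------------------
# Downsampling (voxel integration)


def _cropped_shape(shape, factors):
    return tuple((s // f) * f for s, f in zip(shape, factors))


def downsample(x: np.ndarray, factors, adjoint: bool = False, out_shape=None) -> np.ndarray:
    """Block-average downsampling; adjoint redistributes each value over its cell.

    If the input shape is not divisible by the factors, the trailing edge is
    cropped (forward) or zero-padded (adjoint, to ``out_shape``).
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    if not adjoint:
        cshape = _cropped_shape(x.shape, factors)
        xc = x[tuple(slice(0, c) for c in cshape)]
        ls = tuple(c // f for c, f in zip(cshape, factors))
        xr = xc.reshape(ls[0], factors[0], ls[1], factors[1], ls[2], factors[2])
        return xr.mean(axis=(1, 3, 5))
    # adjoint
    cell = int(np.prod(factors))
    up = x
    for ax, f in enumerate(factors):
        if f > 1:
            up = np.repeat(up, f, axis=ax)
    up = up / cell
    if out_shape is not None and tuple(out_shape) != up.shape:
        pad = np.zeros(out_shape, dtype=up.dtype)
        pad[tuple(slice(0, s) for s in up.shape)] = up
        up = pad
    return up


# ---------------------------------------------------------------------------
# Fourier transform and sampling


def fft3c(x: np.ndarray) -> np.ndarray:
    """Unitary centered 3D FFT over the last three axes (DC at the grid center)."""
    axes = (-3, -2, -1)
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


def ifft3c(k: np.ndarray) -> np.ndarray:
    axes = (-3, -2, -1)
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(k, axes=axes), axes=axes, norm="ortho"), axes=axes
    )


@dataclass(frozen=True)
class SamplingMask:
    """Cartesian k-space sampling mask with acceleration R along one axis."""

    array: np.ndarray
    r: int = 1
    axis: int = 1

    @property
    def num_samples(self) -> int:
        return int(self.array.sum())


def make_undersampling_mask(shape, r: int, axis: int = 1) -> SamplingMask:
    """Keep every ``r``-th phase-encode line, including the central (DC) line."""
    shape = tuple(int(s) for s in shape)
    if not 0 <= axis < 3:
        raise ValueError("axis must index a 3D k-space axis")
    if r < 1 or r > shape[axis]:
        raise ValueError("acceleration factor out of range")
    mask = np.zeros(shape, dtype=bool)
    center = shape[axis] // 2
    lines = [i for i in range(shape[axis]) if (i - center) % r == 0]
    sl = [slice(None)] * 3
    sl[axis] = lines
    mask[tuple(sl)] = True
    return SamplingMask(mask, r=r, axis=axis)


# ---------------------------------------------------------------------------
# Composed per-pair system operator


@dataclass
class AcquisitionModel:
    """The composed per-pair operator E T_i B and its adjoint (Theta = W = I)."""

    shape_high: tuple[int, int, int]
    spacing_high: tuple[float, float, float]
    psf: PSFModel
    transforms: list[RigidTransform]
    factors: tuple[int, int, int]
    coil_maps: np.ndarray  # (L, *shape_low) complex
    mask: np.ndarray | None = None  # bool (*shape_low); None = fully sampled

    def __post_init__(self):
        self.coil_maps = np.asarray(self.coil_maps)
        if self.coil_maps.ndim != 4:
            raise ValueError("coil_maps must be (L, nx, ny, nz)")
        if self.coil_maps.shape[1:] != self.shape_low:
            raise ValueError("coil map grid does not match the low-res grid")
        if self.mask is not None and self.mask.shape != self.shape_low:
            raise ValueError("mask grid does not match the low-res grid")
        if len(self.transforms) < 1:
            raise ValueError("at least one motion state is required")

    @property
    def num_pairs(self) -> int:
        return len(self.transforms)

    @property
    def num_coils(self) -> int:
        return self.coil_maps.shape[0]

    @property
    def shape_low(self) -> tuple[int, int, int]:
        return tuple(
            s // f for s, f in zip(_cropped_shape(self.shape_high, self.factors), self.factors)
        )

    @property
    def spacing_low(self) -> tuple[float, float, float]:
        return tuple(s * f for s, f in zip(self.spacing_high, self.factors))

    def single_state(self, transform: RigidTransform | None = None) -> "AcquisitionModel":
        """Model with a single motion state (used for the M0 reconstruction)."""
        return replace(self, transforms=[transform or RigidTransform()])

    def forward_pair(self, x: np.ndarray, i: int) -> np.ndarray:
        return forward_pair(x, self, i)

    def adjoint_pair(self, d: np.ndarray, i: int) -> np.ndarray:
        return adjoint_pair(d, self, i)


def forward_pair(x: np.ndarray, model: AcquisitionModel, i: int) -> np.ndarray:
    """(I_L (x) Phi F) C D M_i B x -> multi-coil k-space (L, *shape_low)."""
    if x.shape != tuple(model.shape_high):
        raise ValueError(f"expected image of shape {model.shape_high}, got {x.shape}")
    v = apply_blur(x, model.psf)
    v = apply_rigid(v, model.transforms[i], model.spacing_high)
    v = downsample(v, model.factors)
    k = fft3c(model.coil_maps * v[None])
    if model.mask is not None:
        k = k * model.mask
    return k


def adjoint_pair(d: np.ndarray, model: AcquisitionModel, i: int) -> np.ndarray:
    """B' M_i' D' C^H (I_L (x) F^H Phi') d -> high-res image."""
    expected = (model.num_coils,) + model.shape_low
    if d.shape != expected:
        raise ValueError(f"expected k-space of shape {expected}, got {d.shape}")
    k = d * model.mask if model.mask is not None else d
    imgs = ifft3c(k)
    v = np.sum(np.conj(model.coil_maps) * imgs, axis=0)
    v = downsample(v, model.factors, adjoint=True, out_shape=model.shape_high)
    v = apply_rigid(v, model.transforms[i], model.spacing_high, adjoint=True)
    return apply_blur(v, model.psf, adjoint=True)
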