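"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own operator code paths: direct
sliding-window convolution, scipy.ndimage.affine_transform resampling, loop
block averaging, and explicitly assembled DFT matrices.
"""

import numpy as np
from scipy.ndimage import affine_transform


def direct_separable_convolve(x, kernels):
    """Triple-loop sliding-window separable convolution with zero boundaries."""
    out = np.zeros_like(x, dtype=complex)
    radii = [(len(k) - 1) // 2 for k in kernels]
    nx, ny, nz = x.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                for a in range(-radii[0], radii[0] + 1):
                    if not 0 <= i - a < nx:
                        continue
                    for b in range(-radii[1], radii[1] + 1):
                        if not 0 <= j - b < ny:
                            continue
                        for c in range(-radii[2], radii[2] + 1):
                            if not 0 <= k - c < nz:
                                continue
                            acc += (
                                kernels[0][radii[0] + a]
                                * kernels[1][radii[1] + b]
                                * kernels[2][radii[2] + c]
                                * x[i - a, j - b, k - c]
                            )
                out[i, j, k] = acc
    return out


def block_average_loop(x, factors):
    """Loop-based block averaging over factor-sized cells."""
    ls = tuple(s // f for s, f in zip(x.shape, factors))
    out = np.zeros(ls, dtype=x.dtype)
    for i in range(ls[0]):
        for j in range(ls[1]):
            for k in range(ls[2]):
                cell = x[
                    i * factors[0] : (i + 1) * factors[0],
                    j * factors[1] : (j + 1) * factors[1],
                    k * factors[2] : (k + 1) * factors[2],
                ]
                out[i, j, k] = cell.mean()
    return out


def resample_affine_oracle(x, transform, spacing, inverse=False):
    """Rigid resampling via scipy.ndimage.affine_transform (trilinear)."""
    r, t = transform.matrix()
    if inverse:
        a, tv = r, t
    else:
        a, tv = r.T, -(r.T @ t)
    sp = np.asarray(spacing, dtype=float)
    c = (np.asarray(x.shape) - 1) / 2.0 * sp
    mat = np.diag(1.0 / sp) @ a @ np.diag(sp)
    off = (a @ (-c) + tv + c) / sp

    def run(arr):
        return affine_transform(arr, mat, offset=off, order=1, mode="grid-constant", cval=0.0)

    if np.iscomplexobj(x):
        return run(x.real) + 1j * run(x.imag)
    return run(x)


def dense_interp_matrix_oracle(shape, spacing, transform, inverse=False):
    """Dense interpolation matrix assembled column-by-column via affine_transform."""
    n = int(np.prod(shape))
    mat = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = 1.0
        mat[:, j] = resample_affine_oracle(
            e.reshape(shape), transform, spacing, inverse=inverse
        ).ravel()
    return mat


def centered_dft_matrix(n):
    """Unitary DFT matrix with DC at index n//2 on both sides."""
    idx = np.arange(n) - n // 2
    return np.exp(-2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n)


def oracle_forward_chain(x, model, i):
    """Independent evaluation of the per-pair forward operator.

    Uses direct convolution, affine_transform resampling, loop block
    averaging and explicit DFT matrices.
    """
    kernels = model.psf.kernels()
    v = direct_separable_convolve(x.astype(complex), kernels)
    v = resample_affine_oracle(v, model.transforms[i], model.spacing_high)
    v = block_average_loop(v, model.factors)
    fx, fy, fz = (centered_dft_matrix(n) for n in v.shape)
    k = np.einsum("ai,bj,ck,lijk->labc", fx, fy, fz, model.coil_maps * v[None])
    if model.mask is not None:
        k = k * model.mask
    return k
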