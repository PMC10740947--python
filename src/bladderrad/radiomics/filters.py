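"""Image filter bank: Laplacian-of-Gaussian and undecimated 3D wavelets.

Filtered images are computed on the full volume (so that filter support is
not truncated at the lesion) before any mask-restricted feature computation.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

from .config import WAVELET_SUBBANDS


def _gauss_kernels(sigma: float, truncate: float = 4.0):
    """Matched 1D smoothing and second-derivative-of-Gaussian kernels.

    The second-derivative kernel is forced to zero sum so a constant input
    produces an exactly zero response (no DC leakage from truncation).
    """
    radius = max(int(truncate * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    d2 = phi * (x * x - sigma * sigma) / sigma**4
    d2 -= d2.mean()
    return phi, d2


def apply_log(volume: np.ndarray, spacing, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response at a physical scale.

    ``sigma_mm`` is specified in millimetres and converted to per-axis voxel
    sigmas through ``spacing`` (mm per voxel, same axis order as the array),
    so anisotropic voxels see an isotropic physical kernel.  Separable
    implementation: sum over axes of the second-derivative response
    smoothed along the other axes; physical units (the second derivative
    carries 1/mm^2 through the per-axis sigma).
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    vol = np.asarray(volume, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (vol.ndim,) or np.any(spacing <= 0):
        raise ValueError("spacing must give a positive value per axis")
    sigma_vox = sigma_mm / spacing
    out = np.zeros_like(vol)
    for deriv_axis in range(vol.ndim):
        term = vol
        for axis in range(vol.ndim):
            phi, d2 = _gauss_kernels(sigma_vox[axis])
            kernel = d2 / spacing[axis] ** 2 if axis == deriv_axis else phi
            term = ndimage.correlate1d(term, kernel, axis=axis, mode="reflect")
        out += term
    return out


def apply_wavelet(volume: np.ndarray, wavelet: str = "coif1") -> dict:
    """Single-level undecimated (stationary) separable 3D wavelet transform.

    Returns the 8 sub-bands labelled by the filters applied along the
    (x, y, z) axes in that letter order (L = low-pass, H = high-pass), e.g.
    ``HLL`` filters high-pass along x and low-pass along y and z.  The
    transform is undecimated so every sub-band is voxel-aligned with the
    input (and hence with the lesion mask).  Odd axes are symmetrically
    padded by one voxel for the transform and cropped back.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3 or min(vol.shape) < 2:
        raise ValueError("expected a non-degenerate 3D volume")
    pad = [(0, s % 2) for s in vol.shape]
    padded = np.pad(vol, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    out = {}
    crop = tuple(slice(0, s) for s in vol.shape)
    for key, band in coeffs.items():
        # pywt keys are per-axis (z, y, x) with 'a'pprox / 'd'etail; relabel
        # in x, y, z order with L / H letters.
        label = "".join("L" if c == "a" else "H" for c in key[::-1])
        out[label] = band[crop]
    assert set(out) == set(WAVELET_SUBBANDS)
    return out
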