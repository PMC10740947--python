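"""VOI preprocessing for the segmentation network.

A cuboid volume of interest (VOI) plays the role of the annotator-drawn
box: the tight bounding box of the reference mask dilated by a per-axis
margin plus a random outward jitter per face (the simulated annotator's
variability).  VOI intensities are min-max normalized to [0, 1] over the
3D crop, and each transverse (z) slice is zero-padded to the network's
square input size.  Coordinates are 0-based with half-open boxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VOIBox:
    """Half-open cuboid [zmin, zmax) x [ymin, ymax) x [xmin, xmax)."""

    zmin: int; zmax: int
    ymin: int; ymax: int
    xmin: int; xmax: int

    def __post_init__(self):
        if not (self.zmin < self.zmax and self.ymin < self.ymax and self.xmin < self.xmax):
            raise ValueError("VOI must have positive extent on every axis")
        if min(self.zmin, self.ymin, self.xmin) < 0:
            raise ValueError("VOI must be inside the volume")

    @property
    def slices(self) -> tuple:
        return (slice(self.zmin, self.zmax), slice(self.ymin, self.ymax),
                slice(self.xmin, self.xmax))

    @property
    def shape(self) -> tuple:
        return (self.zmax - self.zmin, self.ymax - self.ymin, self.xmax - self.xmin)

    def contains_mask(self, mask: np.ndarray) -> bool:
        outside = mask.copy()
        outside[self.slices] = False
        return not outside.any()


def voi_from_mask(mask: np.ndarray, margin_vox=(1, 6, 6), jitter: int = 0,
                  rng: np.random.Generator | None = None) -> VOIBox:
    """Simulated annotator VOI around a lesion mask.

    Tight bounding box, dilated by ``margin_vox`` per axis, each face pushed
    further outward by an independent uniform draw in ``0..jitter`` voxels,
    clipped to the volume.  The lesion is always fully contained.
    """
    msk = np.asarray(mask, dtype=bool)
    if not msk.any():
        raise ValueError("mask is empty")
    if jitter > 0 and rng is None:
        raise ValueError("jitter requires an rng")
    idx = np.argwhere(msk)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    margin = np.asarray(margin_vox, dtype=int)
    jit_lo = rng.integers(0, jitter + 1, size=3) if jitter > 0 else np.zeros(3, int)
    jit_hi = rng.integers(0, jitter + 1, size=3) if jitter > 0 else np.zeros(3, int)
    lo = np.maximum(lo - margin - jit_lo, 0)
    hi = np.minimum(hi + margin + jit_hi, msk.shape)
    return VOIBox(int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]), int(lo[2]), int(hi[2]))


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1]; a constant input maps to all zeros (with warning)."""
    vol = np.asarray(volume, dtype=float)
    vmin, vmax = float(vol.min()), float(vol.max())
    if vmax == vmin:
        log.warning("min-max normalization of a constant volume -> zeros")
        return np.zeros_like(vol)
    return (vol - vmin) / (vmax - vmin)


def pad_to_size(slice2d: np.ndarray, n: int) -> np.ndarray:
    """Center a 2D slice in an n x n zero canvas (floor offsets).

    The original voxels are unmodified, so :func:`crop_from_pad` inverts
    the operation exactly.
    """
    arr = np.asarray(slice2d)
    h, w = arr.shape
    if h > n or w > n:
        raise ValueError(f"slice {arr.shape} exceeds target size {n}")
    out = np.zeros((n, n), dtype=arr.dtype)
    oy, ox = (n - h) // 2, (n - w) // 2
    out[oy:oy + h, ox:ox + w] = arr
    return out


def crop_from_pad(padded: np.ndarray, shape: tuple) -> np.ndarray:
    """Inverse of :func:`pad_to_size` for an original 2D shape."""
    h, w = shape
    n = padded.shape[0]
    oy, ox = (n - h) // 2, (n - w) // 2
    return padded[oy:oy + h, ox:ox + w]


def center_crop_voi(voi: VOIBox, n: int, volume_shape: tuple) -> VOIBox:
    """Shrink an oversized VOI to fit the network input (with warning)."""
    z0, z1 = voi.zmin, voi.zmax
    b = [voi.ymin, voi.ymax, voi.xmin, voi.xmax]
    changed = False
    for k, (lo_i, hi_i) in enumerate(((0, 1), (2, 3))):
        extent = b[hi_i] - b[lo_i]
        if extent > n:
            excess = extent - n
            b[lo_i] += excess // 2
            b[hi_i] = b[lo_i] + n
            changed = True
    if changed:
        log.warning("VOI exceeded %dx%d input; center-cropped", n, n)
    return VOIBox(z0, z1, b[0], b[1], b[2], b[3])
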