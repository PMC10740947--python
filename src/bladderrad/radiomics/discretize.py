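"""Fixed-bin-width gray-level discretization.

Levels are 1-based: ``level = floor((x - min_in_mask) / bin_width) + 1``,
so binning is anchored at the in-mask minimum of each image independently.
Shifting an image by an exact multiple of the bin width therefore leaves
the level grid unchanged (texture features are shift-covariant through the
anchor).
"""

from __future__ import annotations

import numpy as np


def discretize(volume, mask, bin_width: float):
    """Return ``(levels, n_levels)``.

    ``levels`` matches the input shape with 0 outside the mask and integer
    levels ``1..n_levels`` inside.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes differ")
    if not msk.any():
        raise ValueError("mask is empty")
    x = vol[msk]
    lev = np.floor((x - x.min()) / bin_width).astype(np.int64) + 1
    out = np.zeros(vol.shape, dtype=np.int64)
    out[msk] = lev
    return out, int(lev.max())
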