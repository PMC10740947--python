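"""First-order (intensity histogram) features.

The 18 standard features of the in-mask intensity distribution.  Skewness is
the population moment ratio m3 / m2^1.5 and kurtosis the non-excess ratio
m4 / m2^2 (a normal sample gives ~3).  Entropy and uniformity operate on the
fixed-bin-width discretized histogram.
"""

from __future__ import annotations

import numpy as np

from .discretize import discretize

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

_EPS = np.spacing(1.0)


def firstorder_features(volume, mask, spacing, bin_width: float = 25.0) -> dict:
    x = np.asarray(volume, dtype=float)[np.asarray(mask, dtype=bool)]
    if x.size < 2:
        raise ValueError("first-order features need at least 2 in-mask voxels")
    voxvol = float(np.prod(np.asarray(spacing, dtype=float)))
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    m3 = np.mean(dev**3)
    m4 = np.mean(dev**4)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    levels, ng = discretize(x, np.ones(n, dtype=bool), bin_width)
    p = np.bincount(levels - 1, minlength=ng) / n
    p = p[p > 0]

    energy = float(np.sum(x**2))
    out = {
        "Energy": energy,
        "TotalEnergy": voxvol * energy,
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
    assert tuple(out) == FIRSTORDER_NAMES
    return out
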