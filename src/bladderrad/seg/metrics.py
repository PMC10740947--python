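"""Per-lesion overlap metrics between predicted and reference masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SegMetrics:
    dsc: float
    recall: float
    precision: float


def seg_metrics(pred_mask, ref_mask) -> SegMetrics:
    """DSC = 2TP/(2TP+FP+FN), recall = TP/(TP+FN), precision = TP/(TP+FP).

    Computed over the full 3D volume.  An empty prediction gives recall 0
    and precision 0 by convention; an empty reference is an error.
    """
    pred = np.asarray(pred_mask, dtype=bool)
    ref = np.asarray(ref_mask, dtype=bool)
    if pred.shape != ref.shape:
        raise ValueError("mask shapes differ")
    if not ref.any():
        raise ValueError("reference mask is empty")
    tp = int(np.sum(pred & ref))
    fp = int(np.sum(pred & ~ref))
    fn = int(np.sum(~pred & ref))
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    recall = tp / (tp + fn)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return SegMetrics(float(dsc), float(recall), float(precision))


def summarize(values) -> dict:
    """Mean +- SD / median / range summary used in the report tables."""
    v = np.asarray(values, dtype=float)
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }
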