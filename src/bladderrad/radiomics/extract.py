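"""Assembly of the full radiomics feature bank.

Default composition: 14 shape features on the original mask, plus
18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM = 93
intensity features on the original image and on each of 11 filtered images
(3 LoG scales + 8 wavelet sub-bands): 14 + 12 x 93 = 1130 features.

Names follow the ``{imageType}_{class}_{FeatureName}`` convention, e.g.
``original_firstorder_Kurtosis`` or
``log-sigma-5-0-mm-3D_gldm_LargeDependenceHighGrayLevelEmphasis``.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from .config import ExtractionConfig
from .discretize import discretize
from .filters import apply_log, apply_wavelet
from .firstorder import firstorder_features
from .shape import shape_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

_BBOX_MARGIN = 1  # texture families only see in-mask voxels; 1 keeps slicing safe


def _bbox_crop(mask: np.ndarray):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - _BBOX_MARGIN, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + _BBOX_MARGIN, mask.shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def _intensity_family_values(image, mask, spacing, cfg: ExtractionConfig) -> OrderedDict:
    out = OrderedDict()
    fo = firstorder_features(image, mask, spacing, cfg.bin_width)
    for k, v in fo.items():
        out[("firstorder", k)] = v
    levels, ng = discretize(image, mask, cfg.bin_width)
    for fam, vals in (
        ("glcm", glcm_features(levels, ng, cfg.glcm_distance)),
        ("glrlm", glrlm_features(levels, ng)),
        ("glszm", glszm_features(levels, ng)),
        ("gldm", gldm_features(levels, ng, cfg.gldm_alpha)),
        ("ngtdm", ngtdm_features(levels, ng)),
    ):
        for k, v in vals.items():
            out[(fam, k)] = v
    return out


def extract_all(volume, mask, spacing, cfg: ExtractionConfig | None = None) -> OrderedDict:
    """Extract the full feature vector for one lesion.

    ``volume`` is the raw (unnormalized) intensity grid; ``mask`` the binary
    lesion mask in the same voxel grid; ``spacing`` the per-axis voxel size
    in mm.  Filters are applied to the full volume before cropping so the
    lesion sees untruncated filter support.  Raises on any non-finite
    feature value, naming the offender.
    """
    cfg = cfg or ExtractionConfig()
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask, dtype=bool)
    if vol.shape != msk.shape:
        raise ValueError("volume and mask shapes differ")
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    if msk.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    spacing = np.asarray(spacing, dtype=float)

    features: "OrderedDict[str, float]" = OrderedDict()
    for name, value in shape_features(msk, spacing).items():
        features[f"original_shape_{name}"] = value

    crop = _bbox_crop(msk)
    images = {"original": vol}
    if cfg.include_log:
        for s, name in zip(cfg.log_sigmas_mm, [t for t in cfg.image_types if t.startswith("log")]):
            images[name] = apply_log(vol, spacing, s)
    if cfg.include_wavelet:
        bands = apply_wavelet(vol, cfg.wavelet)
        for band, img in bands.items():
            images[f"wavelet-{band}"] = img

    msk_c = msk[crop]
    for image_type in cfg.image_types:
        img_c = images[image_type][crop]
        for (fam, name), value in _intensity_family_values(img_c, msk_c, spacing, cfg).items():
            features[f"{image_type}_{fam}_{name}"] = value

    bad = [k for k, v in features.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature values: {bad[:5]}")
    return features


def extract_table(samples, masks=None, cfg: ExtractionConfig | None = None,
                  source: str = "manual") -> pd.DataFrame:
    """Feature table for a list of lesion samples.

    ``samples`` are :class:`bladderrad.phantom.LesionSample` objects; if
    ``masks`` is given (mapping id -> binary mask) those masks replace the
    reference masks (the semi-automatic arm).  Returns a DataFrame indexed
    by lesion id with ``label``/``cohort``/``source`` metadata columns
    followed by the feature columns.
    """
    cfg = cfg or ExtractionConfig()
    rows = []
    meta = []
    for s in samples:
        mask = s.mask if masks is None else masks[s.id]
        if mask.sum() < 2:
            raise ValueError(f"lesion {s.id}: segmentation mask too small for extraction")
        rows.append(extract_all(s.volume, mask, s.spacing, cfg))
        meta.append({"id": s.id, "label": s.label, "cohort": s.cohort, "source": source})
    feat = pd.DataFrame(rows, index=[m["id"] for m in meta])
    md = pd.DataFrame(meta).set_index("id")
    return pd.concat([md, feat], axis=1)


FEATURE_COLUMNS_START = 3  # label, cohort, source


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the metadata columns, keeping only feature values."""
    return table.drop(columns=["label", "cohort", "source"])
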