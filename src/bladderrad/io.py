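"""File interfaces: NIfTI volumes, cohort manifests, YAML configs, reports.

Volumes are written as NIfTI-1 (.nii.gz) with the voxel spacing recorded in
the affine; masks as uint8.  A cohort lives in a directory with one
``<id>_image.nii.gz`` / ``<id>_mask.nii.gz`` pair per lesion plus a
``manifest.csv`` with columns id, label, cohort, volume_path, mask_path.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import LesionSample, PhantomParams


def _affine(spacing) -> np.ndarray:
    # array axes (z, y, x) -> spatial diag; orientation is irrelevant for
    # the synthetic workflow, only the voxel sizes matter
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(path, data: np.ndarray, spacing) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_volume(path):
    """Returns ``(data, spacing)``."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume file not found: {p}")
    img = nib.load(str(p))
    return np.asarray(img.get_fdata()), tuple(float(z) for z in img.header.get_zooms()[:3])


def save_cohort(samples, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        vpath = outdir / f"{s.id}_image.nii.gz"
        mpath = outdir / f"{s.id}_mask.nii.gz"
        save_volume(vpath, s.volume, s.spacing)
        save_volume(mpath, s.mask.astype(np.uint8), s.spacing)
        rows.append({"id": s.id, "label": s.label, "cohort": s.cohort,
                     "volume_path": vpath.name, "mask_path": mpath.name})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    samples = []
    for _, row in pd.read_csv(manifest_path).iterrows():
        vol, spacing = load_volume(base / row["volume_path"])
        msk, _ = load_volume(base / row["mask_path"])
        samples.append(LesionSample(
            id=row["id"], volume=vol, mask=msk > 0.5, label=row["label"],
            spacing=spacing, cohort=row["cohort"]))
    return samples


def save_params_yaml(params: PhantomParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_params_yaml(path) -> PhantomParams:
    return PhantomParams.from_dict(yaml.safe_load(Path(path).read_text()))


def save_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
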