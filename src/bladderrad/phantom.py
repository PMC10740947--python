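"""Synthetic 3D bladder-lesion phantoms.

The generator emulates the class contrasts that drive the downstream
analysis on T2-weighted-like volumes: muscle-invasive (MIBC) lesions are
less spherical (stronger boundary perturbation, mirroring their irregular
infiltrative margins), larger, and show a more skewed / heavier-tailed
in-lesion intensity histogram than non-muscle-invasive (NMIBC) lesions.
Each lesion occupies a small sub-volume of a larger anisotropic grid, with
a dimmer rim around it standing in for bladder-wall contrast.

Shape model: an ellipsoid with random axis ratios whose boundary radius is
modulated by low-order (l = 2..6) real spherical-harmonic perturbations;
the perturbation amplitude is the per-class sphericity knob.  Intensity
model: skew-normal voxels (shape = per-class skewness knob) mixed with a
heavy-tailed Student-t component (weight = per-class kurtosis knob) on a
noisy constant background.

Array axis order is (z, y, x) with voxel spacing in mm given in the same
order; the default grid is 32 x 96 x 96 voxels at 3.0 x 0.8 x 0.8 mm
(axial-T2-like anisotropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y
from scipy.stats import skewnorm

NMIBC, MIBC = "NMIBC", "MIBC"
LESION_CLASSES = (NMIBC, MIBC)
COHORTS = ("train", "internal", "external")

#: class-count defaults of the emulated study
COHORT_COUNTS = {"train": (103, 26), "internal": (27, 4), "external": (23, 32)}

_RETRY_CAP = 50


@dataclass
class ClassParams:
    """Per-class shape / intensity knobs."""

    base_radius_mm: float
    radius_jitter: float = 0.20
    boundary_perturb_amp: float = 0.05
    intensity_skew: float = 0.0
    intensity_kurtosis_mix: float = 0.0

    def __post_init__(self):
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be positive")
        if self.boundary_perturb_amp < 0:
            raise ValueError("boundary_perturb_amp must be non-negative")
        if not 0.0 <= self.intensity_kurtosis_mix <= 1.0:
            raise ValueError("intensity_kurtosis_mix must lie in [0, 1]")


@dataclass
class PhantomParams:
    """Cohort-level phantom parameters.

    Defaults encode the intended class contrasts: MIBC gets the larger
    boundary-perturbation amplitude (lower sphericity), the larger skew
    shape and the larger heavy-tail weight (higher kurtosis), plus a
    larger base radius (mirroring the predominance of >= 3 cm lesions in
    the invasive class).
    """

    nmibc: ClassParams = field(default_factory=lambda: ClassParams(
        base_radius_mm=7.5, radius_jitter=0.30, boundary_perturb_amp=0.05,
        intensity_skew=0.5, intensity_kurtosis_mix=0.02))
    mibc: ClassParams = field(default_factory=lambda: ClassParams(
        base_radius_mm=10.5, radius_jitter=0.30, boundary_perturb_amp=0.20,
        intensity_skew=4.0, intensity_kurtosis_mix=0.20))
    volume_shape: tuple = (32, 96, 96)
    spacing_mm: tuple = (3.0, 0.8, 0.8)
    background_level: float = 100.0
    noise_sd: float = 10.0
    # per-lesion intensity level/scale draws emulate the arbitrary
    # acquisition scaling of T2-W MRI (intensities are not standardized
    # across patients)
    lesion_level_range: tuple = (150.0, 220.0)
    lesion_scale_range: tuple = (18.0, 40.0)
    rim_contrast: float = 0.6
    rim_width_vox: int = 2
    axis_ratio_range: tuple = (0.75, 1.3)
    harmonic_orders: tuple = (2, 3, 4, 5, 6)
    #: lesions larger than this in-plane are rejected and redrawn, so every
    #: phantom fits an annotator VOI sized for the segmentation input
    max_inplane_extent_mm: float = 40.0

    def __post_init__(self):
        if self.mibc.boundary_perturb_amp <= self.nmibc.boundary_perturb_amp:
            raise ValueError("MIBC must have the larger boundary perturbation")
        if self.mibc.intensity_skew <= self.nmibc.intensity_skew:
            raise ValueError("MIBC must have the larger intensity skew")
        if any(s <= 0 for s in self.spacing_mm) or self.noise_sd < 0:
            raise ValueError("scale parameters must be positive")

    def for_label(self, label: str) -> ClassParams:
        if label == NMIBC:
            return self.nmibc
        if label == MIBC:
            return self.mibc
        raise ValueError(f"unknown lesion class {label!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        for key in ("nmibc", "mibc"):
            if key in d and isinstance(d[key], dict):
                d[key] = ClassParams(**d[key])
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


@dataclass
class LesionSample:
    """One synthetic lesion: intensities, reference mask and metadata."""

    id: str
    volume: np.ndarray
    mask: np.ndarray
    label: str
    spacing: tuple
    cohort: str

    def __post_init__(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError("volume and mask shapes differ")
        if self.label not in LESION_CLASSES:
            raise ValueError(f"unknown lesion class {self.label!r}")


def _real_harmonic_basis(orders, theta, phi, coeffs):
    """Random low-order angular perturbation field on given directions."""
    field_vals = np.zeros(theta.shape)
    k = 0
    for l in orders:
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            field_vals += coeffs[k] * y.real
            k += 1
            if m > 0:
                field_vals += coeffs[k] * y.imag
                k += 1
    return field_vals


def _n_harmonic_coeffs(orders) -> int:
    return sum(2 * l + 1 for l in orders)


def sample_shape(label: str, params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    """Draw one lesion mask: perturbed random ellipsoid inside the grid.

    Rejects and resamples (up to a cap) draws that would leave the volume,
    come out empty, or disconnect; with the default low-order harmonics the
    radius stays positive, so the blob is star-shaped and 26-connected.
    """
    cp = params.for_label(label)
    shape = np.asarray(params.volume_shape)
    spacing = np.asarray(params.spacing_mm, dtype=float)
    orders = params.harmonic_orders
    structure = np.ones((3, 3, 3), dtype=int)

    for _ in range(_RETRY_CAP):
        radius = cp.base_radius_mm * (1.0 + cp.radius_jitter * (2 * rng.random() - 1))
        ratios = rng.uniform(*params.axis_ratio_range, size=3)
        semi = radius * ratios / np.cbrt(np.prod(ratios))  # volume-preserving
        n_coef = _n_harmonic_coeffs(orders)
        # normalized so the angular field has sd ~ amp (fraction of radius):
        # by the addition theorem the real/imag basis squares sum to about
        # sum_l (2l+1) / (8 pi) over a sphere
        sigma_c = cp.boundary_perturb_amp * np.sqrt(
            8.0 * np.pi / sum(2 * l + 1 for l in orders))
        coeffs = rng.normal(0.0, sigma_c, size=n_coef)

        max_ext = semi.max() * (1.0 + 4 * cp.boundary_perturb_amp)
        margin_vox = np.ceil(max_ext / spacing).astype(int) + 1
        if np.any(2 * margin_vox + 2 >= shape):
            continue  # lesion cannot fit; resample a smaller draw
        center = np.array([
            rng.integers(margin_vox[a], shape[a] - margin_vox[a]) for a in range(3)
        ])

        lo = center - margin_vox
        hi = center + margin_vox + 1
        zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d = np.stack([(zz - center[0]) * spacing[0],
                      (yy - center[1]) * spacing[1],
                      (xx - center[2]) * spacing[2]])
        u = d / semi[:, None, None, None]
        rho = np.sqrt((u**2).sum(axis=0))
        # harmonics are only needed on the shell that the perturbation can
        # reach; |field| beyond 4 amp-sd is vanishingly rare and clipped
        bound = 4.0 * cp.boundary_perturb_amp
        local = rho <= 1.0 - bound
        band = (rho > 1.0 - bound) & (rho <= 1.0 + bound)
        if band.any() and bound > 0:
            ub = u[:, band]
            rb = rho[band]
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = np.arccos(np.clip(ub[0] / np.maximum(rb, 1e-12), -1, 1))
                phi = np.mod(np.arctan2(ub[1], ub[2]), 2 * np.pi)
            perturb = _real_harmonic_basis(orders, theta, phi, coeffs)
            local[band] = rb <= 1.0 + perturb

        if not local.any():
            continue
        lab, n = ndimage.label(local, structure=structure)
        if n > 1:  # keep it simple: require a single connected draw
            continue
        idx = np.argwhere(local)
        extent_mm = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
        if max(extent_mm[1], extent_mm[2]) > params.max_inplane_extent_mm:
            continue
        mask = np.zeros(tuple(shape), dtype=bool)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = local
        return mask
    raise RuntimeError(f"could not fit a {label} lesion into the volume "
                       f"after {_RETRY_CAP} draws")


def sample_intensity(mask: np.ndarray, label: str, params: PhantomParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw the intensity volume for a lesion mask.

    Background: ``background_level`` + N(0, noise_sd).  A rim of
    ``rim_width_vox`` dilations around the lesion is dimmed by
    ``rim_contrast`` (bladder-wall analog).  In-mask: skew-normal (shape =
    per-class skew) mixed with a scaled Student-t (df = 5) component with
    the per-class weight (raising kurtosis without moving the skewness
    knob), placed at a per-lesion level and scale drawn uniformly from
    ``lesion_level_range`` / ``lesion_scale_range``.
    """
    msk = np.asarray(mask, dtype=bool)
    if not msk.any():
        raise ValueError("mask is empty")
    cp = params.for_label(label)
    vol = np.full(msk.shape, float(params.background_level))
    if params.noise_sd > 0:
        vol += rng.normal(0.0, params.noise_sd, size=msk.shape)

    if params.rim_width_vox > 0:
        dil = ndimage.binary_dilation(msk, np.ones((3, 3, 3), bool),
                                      iterations=params.rim_width_vox)
        rim = dil & ~msk
        vol[rim] *= params.rim_contrast

    n = int(msk.sum())
    a = cp.intensity_skew
    core = skewnorm.rvs(a, size=n, random_state=rng)
    # re-center/scale so the skew-normal core keeps mean 0, unit variance
    delta = a / np.sqrt(1 + a * a)
    mu = delta * np.sqrt(2 / np.pi)
    sd = np.sqrt(1 - mu * mu)
    core = (core - mu) / sd
    if cp.intensity_kurtosis_mix > 0:
        heavy = rng.standard_t(df=5, size=n) / np.sqrt(5.0 / 3.0)
        pick = rng.random(n) < cp.intensity_kurtosis_mix
        core = np.where(pick, heavy, core)
    level = rng.uniform(*params.lesion_level_range)
    scale = rng.uniform(*params.lesion_scale_range)
    vol[msk] = level + scale * core
    return vol


def generate_cohort(n_nmibc: int, n_mibc: int, cohort: str,
                    params: PhantomParams | None = None,
                    seed: int = 0) -> list:
    """Generate a labelled cohort of lesions (NMIBC first, then MIBC).

    Fully deterministic given ``(params, seed)``: every lesion draws from
    its own child stream of a single seed sequence.
    """
    if n_nmibc < 0 or n_mibc < 0:
        raise ValueError("counts must be non-negative")
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    params = params or PhantomParams()
    labels = [NMIBC] * n_nmibc + [MIBC] * n_mibc
    streams = np.random.SeedSequence(seed).spawn(len(labels))
    samples = []
    counters = {NMIBC: 0, MIBC: 0}
    for lab, ss in zip(labels, streams):
        rng = np.random.default_rng(ss)
        mask = sample_shape(lab, params, rng)
        vol = sample_intensity(mask, lab, params, rng)
        counters[lab] += 1
        samples.append(LesionSample(
            id=f"{cohort}-{lab.lower()}-{counters[lab]:03d}",
            volume=vol, mask=mask, label=lab,
            spacing=tuple(params.spacing_mm), cohort=cohort,
        ))
    return samples


def scaled_counts(scale: float) -> dict:
    """Cohort class counts scaled from the emulated study's sizes.

    Counts are rounded with a floor of 1 lesion per class (2 per class in
    the training cohort so stratified fitting stays possible).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    out = {}
    for cohort, (n0, n1) in COHORT_COUNTS.items():
        floor = 2 if cohort == "train" else 1
        out[cohort] = (max(floor, round(n0 * scale)), max(floor, round(n1 * scale)))
    return out
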