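# Methods

`bladderrad` implements a paired comparison of two radiomics pipelines for
predicting muscle invasion in bladder cancer from T2-weighted-like 3D
volumes: one arm extracts features from reference ("manual") lesion masks,
the other from masks predicted by a deep segmentation network inside an
annotator-supplied box ("semi-automatic"). The question the statistics
answer is not which arm is better but whether they are *equivalent* —
whether the 95% CI of the difference of their ROC AUCs lies inside a
pre-declared margin.

## Synthetic lesion phantoms

Real bladder MRI is not distributed with this package; the study runs on
seeded synthetic phantoms whose class contrasts carry the discriminative
structure the pipeline must detect.

**Shape.** A lesion is an ellipsoid with random axis ratios (volume-
preserving, ratios uniform in 0.75–1.3) whose boundary radius is modulated
by a random linear combination of real spherical harmonics of orders 2–6.
Coefficients are normalized so `boundary_perturb_amp` equals the standard
deviation of the fractional radial perturbation; because the field is
low-order and bounded, the blob stays star-shaped and 26-connected.
Draws whose in-plane extent exceeds `max_inplane_extent_mm` (default
40 mm) are rejected and redrawn, so every lesion fits the annotator box
at the configured network input size; a draw that cannot fit after 50
attempts raises. Defaults: non-invasive (NMIBC) lesions
`base_radius 7.5 mm`, perturbation sd 0.05; invasive (MIBC) lesions
`base_radius 10.5 mm`, perturbation sd 0.20; radius jitter ±30% both.
Invasive lesions are therefore larger and markedly less spherical,
matching the direction of the shape contrasts the classifier is meant to
exploit.

**Intensity.** Background is constant (default 100) plus Gaussian noise
(sd 10, arbitrary units); a 2-voxel dilation ring around the lesion is
dimmed by factor 0.6 as a bladder-wall analog (the ring is part of the
background; with zero noise the non-ring background equals the background
level exactly). In-mask voxels are drawn from a standardized skew-normal
(shape parameter = per-class `intensity_skew`: 0.5 NMIBC vs 4.0 MIBC)
mixed with a scaled Student-t (df 5) component with per-class weight
(0.02 vs 0.20) that raises kurtosis without moving the skewness knob.
Each lesion draws its own intensity level (uniform 150–220) and scale
(uniform 18–40): T2-weighted intensities are not standardized across
acquisitions, and this between-lesion variability is what gives
per-feature agreement statistics (ICC) a realistic between-subject
variance to work against.

**Grids.** Default volume 32×96×96 voxels (z, y, x) at 3.0×0.8×0.8 mm —
the anisotropy of axial T2-weighted imaging at desk scale. Cohort class
counts default to the emulated study (train 103/26, internal 27/4,
external 23/32 NMIBC/MIBC) and scale multiplicatively with a floor of
one (train: two) lesion per class.

**What the phantoms do not emulate:** bladder anatomy and neighboring
organs, multi-coil bias fields, partial-volume effects at the wall,
scanner- or center-specific texture, multifocal disease, or any spatial
correlation structure inside the lesion beyond what the rim provides.
Passing tests therefore show the *pipeline* recovers planted contrasts of
the reported kind at desk scale; they say nothing about effect sizes on
clinical MRI.

## Semi-automatic segmentation

The simulated annotator draws a cuboid VOI: the mask's tight bounding box
dilated by a per-axis margin (default 1 voxel in z, 5 in-plane) plus an
outward uniform jitter of 0–2 voxels per face, clipped to the volume. VOI
intensities are min-max normalized to [0, 1] over the 3D crop (a constant
crop maps to zeros, with a warning), and each transverse slice is
zero-padded to the square network input, centered with floor offsets. A
VOI wider than the input is center-cropped with a warning; phantom sizes
are chosen so this is rare.

The network is a 2D U-Net: five double-conv blocks (two 3×3
convolutions, each followed by batch normalization and ReLU) with four
2×2 max-poolings in the encoder; four decoder stages of 4×4/stride-2
transpose convolution, skip concatenation, and a double-conv block; and a
1×1 convolution + sigmoid head. Channel width doubles per depth from
`base_channels` (64 canonical; 8 in the desk profile). A 256-square input
reaches a 16-square bottleneck. The implementation is plain numpy
(channel-last, im2col + BLAS matmuls, hand-written backward passes) and
is verified against numerical differentiation end to end; training is
bit-reproducible given the seed.

Training minimizes `w_f * focal + w_d * softDice` (defaults 1 and 1;
focal γ=2, α=0.25 — the standard defaults of the focal-loss
formulation — Dice smooth 1), with Adam (L2 weight decay 1e-4 applied to
weight matrices only) and per-epoch cosine annealing of the learning rate
from 1e-3 to 1e-5; batches of 20 slices are pooled across lesions and
reshuffled every epoch. All slices inside each VOI participate, including
tumor-free ones introduced by the jitter. Inference reuses the identical
preprocessing, crops the padded probability maps back into VOI
coordinates (outside the VOI is background by construction), thresholds
at 0.5, and keeps the largest 26-connected component to suppress
speckle. Per-lesion DSC, recall and precision are computed over the full
3D volume.

## Radiomics feature bank

1130 features per lesion: 14 shape features on the arm's mask geometry
plus 93 intensity features (18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM) on each of 12 images — the original plus
Laplacian-of-Gaussian responses at σ ∈ {1, 3, 5} mm and the 8 sub-bands
of a single-level undecimated coiflet-1 wavelet transform. Feature
definitions and names follow the IBSI/pyradiomics conventions
(`{imageType}_{class}_{FeatureName}`); kurtosis is the non-excess moment
ratio. Features are computed on raw (unnormalized) intensities from the
full-resolution volume restricted by the mask; the [0,1] normalization
belongs to the segmentation network only.

Numerical choices worth noting:

- **Discretization**: fixed bin width (default 25 intensity units),
  anchored at the in-mask minimum of each image independently; texture
  features are therefore invariant to intensity shifts by exact bin
  multiples and covariant otherwise.
- **Aggregation**: GLCM/GLRLM matrices are built per direction (13 unique
  3D offsets, symmetric accumulation) and features averaged across
  directions; directions with no valid voxel pairs are skipped.
- **Degenerate regions**: single-gray-level regions use the limit
  conventions (GLCM correlation and MCC → 1, NGTDM contrast → 0,
  coarseness capped at 1e6); any non-finite feature raises with the
  feature's name rather than propagating NaN.
- **GLDM**: dependence tolerance α=0; the dependence *size* is the
  dependent-neighbour count + 1.
- **Meshing**: surface area and mesh volume come from marching cubes
  (level 0.5) on the bounding-box crop of a mildly Gaussian-smoothed
  (σ=0.8 voxel) occupancy map. Raw binary meshing overstates the area of
  a digital sphere by ~8% (staircase bevel), which would bias sphericity
  to ~0.92 for a perfect sphere; with the antialiased mesh a digital
  r=20 sphere reads 0.997. The trade-off is that sharp-edged objects read
  slightly more spherical than their ideal closed form (a 10-voxel cube:
  0.90 vs the sharp 0.81) — acceptable here because lesions are smooth
  blobs. Meshing the crop also makes shape features exactly
  translation-invariant.
- **LoG**: separable second-derivative-of-Gaussian kernels with the
  second-derivative kernel forced to zero sum, so constant volumes give
  an exactly zero response; sigma is physical (mm), converted per axis.
- **Wavelet**: stationary (undecimated) transform so sub-bands stay
  voxel-aligned with the mask; odd axes are symmetrically padded by one
  voxel and cropped back. Sub-band letters are ordered (x, y, z).

Every texture family is validated against an independent brute-force
enumeration (plain loops over voxel pairs, runs, flood-filled zones,
neighborhoods) to 1e-9 on randomized grids.

## Selection and classification

Per arm, fitted strictly on the training cohort: Z-score standardization
(population-SD convention; zero-variance features dropped with a
warning), then an L1-penalized logistic path over 100 log-spaced λ values
spanning 4 decades down from λ_max (the smallest fully-shrinking
penalty), scored by stratified cross-validated binomial deviance
(10 folds, capped at the minority class count) with λ* at the minimum;
the non-zero-coefficient features at λ* feed an RBF-SVM grid-searched
over C ∈ 2^{-3..7}, γ ∈ 2^{-9..1} by stratified CV AUC (ties resolve to
the smallest C then γ), refitted with Platt sigmoid calibration on
training folds. Validation cohorts are transformed with training
parameters only; nothing downstream of the split ever sees validation
labels. The linear-LASSO variant is retained solely because its
orthonormal-design soft-threshold solution provides a closed-form test
oracle.

## Statistics

- **AUC**: Mann-Whitney pair counting with half credit for ties; variance
  by DeLong's structural components (midrank formulation); 95% normal CI
  clipped to [0,1]. A perfectly separating score vector has zero DeLong
  variance; its CI lower bound is then the conservative distribution-free
  value `0.05^(1/min(n_pos, n_neg))` and the result is flagged
  `degenerate` — the choice matters only for display, not for any
  equivalence verdict.
- **Paired comparison**: DeLong's paired test; the equivalence verdict is
  `CI_95(AUC_A − AUC_B) ⊂ (−Δ, +Δ)` with margin Δ = 0.05.
- **Operating point**: the Youden-maximizing threshold over midpoints of
  adjacent distinct scores, ties broken toward the lower threshold
  (favoring sensitivity); the cutoff is derived on the training cohort
  and applied unchanged to the validation cohorts.
- **Paired accuracy**: exact binomial McNemar on discordant pairs.
- **Feature agreement**: per-feature ICC between the two arms' raw
  feature tables over all lesions — two-way mixed effects, absolute
  agreement, single measurement — summarized by median and IQR.
- **Sample size**: Hanley-McNeil binormal-exponential SE; smallest n_pos
  with `z_{α/2}·SE₀ + z_β·SE₁ ≤ AUC_alt − 0.5`,
  `n_neg = floor(ratio·n_pos)` (≥1).
- **Group tests**: Mann-Whitney U (exact for combined n ≤ 12 without
  ties), with a Shapiro-Wilk/KS normality screen available for cohort
  summaries.

## Desk profile and problem sizes

The full-scale configuration (256-px input, 64 base channels, 100
epochs, unscaled cohorts) is expressed in the defaults but is not what
the test suite runs. The desk profile used throughout testing and in
`scripts/acceptance.py` is: cohort scale 0.25 (train 26/7, internal 7/1,
external 6/8), 64-px slices, 8 base channels, 8 training epochs, and a
z-tight VOI (margin 0/5/5 voxels, face jitter 1). At
this size one end-to-end study takes on the order of two minutes on a
single CPU, the trained segmenter reaches validation DSC ≈ 0.9, both
arms separate the external cohort essentially perfectly, and the paired
AUC difference is tightly centered on zero — the qualitative pattern of
the full-scale study, at sample sizes where "AUC = 1.0" should be read
as "no observed discordant pair", not as a clinical claim.

## Known limitations

- The desk-scale validation cohorts are small; the internal cohort at
  scale 0.25 contains a single invasive lesion, so its AUC and CI are
  reported but fragile by construction.
- The equivalence CI at desk scale is frequently the degenerate [0, 0]
  (both arms rank the external cohort identically); the machinery is
  exercised more informatively by the unit tests with constructed score
  vectors.
- Probability calibration uses Platt scaling on training folds; absolute
  probability cutoffs are therefore comparable between arms but not
  calibrated in the clinical sense.
- The numpy U-Net is single-threaded and memory-bandwidth-bound; it is
  not intended for full-resolution training, only for faithful
  architecture/loss semantics at desk scale.
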