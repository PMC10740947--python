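# bladderrad

Radiomics prediction of muscle invasion in bladder cancer, comparing a
**semi-automatic** (deep-learning) lesion segmentation against **manual**
segmentation — with the statistical machinery to decide whether the two
resulting diagnostic models are *equivalent*.

Bladder cancer management splits on one preoperative question: has the
tumor invaded the muscularis propria (MIBC) or not (NMIBC)? Radiomics
models answer it from T2-weighted MRI, but they classically require a
radiologist to contour every lesion by hand. This package implements the
full alternative workflow — a 2D U-Net that segments the lesion inside a
quickly-drawn cuboid box, an IBSI-style bank of 1130 quantitative features
(shape, first-order histogram, and five gray-level texture families on the
original, Laplacian-of-Gaussian and 3D wavelet images), LASSO feature
selection and an RBF-kernel SVM — *twice*, once per segmentation source,
and then asks the statistical question properly:

- AUC with DeLong variance: the AUC estimate is the Mann-Whitney statistic
  U/(n₊n₋), its variance from DeLong structural components;
- paired AUC difference d = AUC_semi − AUC_manual with its 95% CI;
- **equivalence**: the two models are declared equivalent iff
  CI₉₅(d) ⊂ (−Δ, +Δ) with margin Δ = 0.05;
- exact McNemar on paired correctness, Youden operating points,
  per-feature ICC (two-way mixed, absolute agreement) between the arms,
  and Hanley-McNeil ROC sample-size planning.

Because clinical MRI cannot be redistributed, the package ships a seeded
synthetic-phantom module: 3D lesions with spherical-harmonic-perturbed
boundaries and skew-normal/heavy-tailed intensity histograms whose class
contrasts (invasive lesions larger, less spherical, with more skewed and
heavier-tailed histograms) mirror the discriminative features reported for
real cohorts. Everything — cohorts, training, selection, statistics — is
deterministic given a seed.

Audience: medical-image-analysis researchers who want a tested,
end-to-end reference implementation of the paired two-arm radiomics
design, or any of its parts (the feature bank and the DeLong/equivalence
statistics are usable stand-alone).

## Worked example

```python
from bladderrad import MuscleInvasionStudy, StudyConfig

cfg = StudyConfig.desk_profile(scale=0.25, seed=42)
result = MuscleInvasionStudy(cfg).fit()
print(result.summary())
```

prints (about two minutes on one CPU):

```
Muscle-invasion radiomics study: semi-automatic vs manual segmentation
==========================================================================
seed 42  scale 0.25  net 64px/8ch  epochs 8  features 1130

Segmentation (semi-automatic vs reference)
  internal  DSC 0.904 +- 0.022 (median 0.902, n=8)
  external  DSC 0.903 +- 0.069 (median 0.916, n=14)

Classification (probability of muscle invasion)
  internal  manual    AUC 1.000 (0.050-1.000)  acc 1.000 sens 1.000 spec 1.000
  internal  semiauto  AUC 1.000 (0.050-1.000)  acc 1.000 sens 1.000 spec 1.000
  external  manual    AUC 1.000 (0.607-1.000)  acc 1.000 sens 1.000 spec 1.000
  external  semiauto  AUC 1.000 (0.607-1.000)  acc 1.000 sens 1.000 spec 1.000

Equivalence (margin +-0.05)
  internal  dAUC +0.000 (+0.000 to +0.000)  EQUIVALENT; DeLong p 1.000; McNemar p 1.000
  external  dAUC +0.000 (+0.000 to +0.000)  EQUIVALENT; DeLong p 1.000; McNemar p 1.000

Feature agreement: median ICC 0.914 (IQR 0.755-0.960) over 1130 features
  manual: 14 selected features (lambda* 0.0001)
  semiauto: 16 selected features (lambda* 0.0001)
```

Reading it: the network segments held-out lesions at mean DSC ≈ 0.90
against the reference masks; both radiomics models separate invasive from
non-invasive lesions perfectly at this (small) desk scale, so the paired
AUC difference is 0 with a degenerate CI inside ±0.05 and the arms are
declared equivalent; the 1130 features agree between the two mask sources
with median ICC 0.91. At desk-scale cohort sizes (7/1 internal, 6/8
external) "AUC 1.000" means *no discordant pair was observed*, and the
reported CI lower bounds are correspondingly wide.

`result.save(outdir)` writes the report files (segmentation metrics CSV,
per-arm feature tables and selected-feature reports with per-cohort
Mann-Whitney p-values, performance/equivalence JSON, per-feature ICC CSV,
run manifest). The same pipeline is scriptable from the shell:

```bash
bladderrad synth --out data --seed 1 --scale 0.25
bladderrad train-seg --data data --out model --seed 1
bladderrad segment --model model/segmenter.pkl --data data --out preds
bladderrad extract --data data --out features_manual.csv --source manual
bladderrad extract --data data --out features_semi.csv --source semiauto --masks preds
bladderrad reproduce-study --out study_out --seed 42 --scale 0.25
```

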