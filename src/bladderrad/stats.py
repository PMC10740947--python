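"""ROC and agreement statistics for paired radiomics-model comparison.

This module collects the evaluation machinery used to compare two diagnostic
models scored on the same cases:

* nonparametric AUC with DeLong's structural-component variance and a
  normal-approximation 95% CI,
* DeLong's paired test for the difference of two correlated AUCs,
* a CI-based equivalence test (equivalent iff the 95% CI of the paired AUC
  difference lies strictly inside ``(-margin, +margin)``),
* the Youden-index operating cutoff and confusion metrics,
* exact (binomial) McNemar's test on paired classification correctness,
* per-feature intraclass correlation (two-way mixed effects, absolute
  agreement, single measurement),
* Mann-Whitney U and a small normality gate (Shapiro-Wilk / KS),
* Hanley-McNeil ROC sample-size estimation against a null AUC of 0.5.

Throughout, the positive class is coded 1 (here: muscle-invasive disease).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "EquivalenceResult",
    "ICCResult",
    "SampleSizeResult",
    "auc",
    "delong_paired_test",
    "equivalence_auc",
    "youden_cutoff",
    "confusion_at_cutoff",
    "mcnemar_exact",
    "icc_absolute_agreement",
    "icc_features",
    "mann_whitney",
    "normality_test",
    "auc_sample_size",
]


# ---------------------------------------------------------------------------
# AUC / DeLong machinery
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """AUC with DeLong variance and 95% CI.

    ``degenerate`` flags a perfectly separating score vector, for which the
    DeLong variance collapses to 0; the CI lower bound is then a conservative
    distribution-free bound (see :func:`auc`).
    """

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    degenerate: bool = False


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("labels must be coded 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return labels.astype(int)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties share the average rank)."""
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative).

    Uses the midrank formulation: for positive i,
    V10_i = P(score+ > score-) + 0.5 P(=) estimated over all negatives.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    rank_all = _midrank(np.concatenate([pos, neg]))
    rank_pos = _midrank(pos)
    rank_neg = _midrank(neg)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    return v10, v01


def auc(scores, labels) -> ROCResult:
    """Mann-Whitney AUC with DeLong variance and clipped 95% CI.

    Ties between a positive and a negative score receive half credit.  For a
    perfectly separating score vector the DeLong variance is 0; the CI is then
    reported as ``[alpha**(1/min(n_pos, n_neg)), 1]`` — the one-sided 95%
    lower bound obtained by treating the min(n_pos, n_neg) independent
    positive/negative comparisons as Bernoulli trials that all succeeded —
    and the result is flagged ``degenerate``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    a = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    if var > 0:
        se = np.sqrt(var)
        z = sps.norm.ppf(0.975)
        lo, hi = max(0.0, a - z * se), min(1.0, a + z * se)
        degenerate = False
    else:
        k = min(m, n)
        if a >= 1.0:
            lo, hi = 0.05 ** (1.0 / k), 1.0
        elif a <= 0.0:
            lo, hi = 0.0, 1.0 - 0.05 ** (1.0 / k)
        else:  # constant scores: AUC 0.5 with no spread information
            lo, hi = 0.0, 1.0
        degenerate = True
    return ROCResult(a, var, lo, hi, m, n, scores, labels.astype(int), degenerate)


def delong_paired_test(scores_a, scores_b, labels):
    """DeLong's paired test for correlated AUCs on identical cases.

    Returns ``(difference, variance_of_difference, z, p_two_sided)``.
    When the variance of the difference is exactly 0 (e.g. identical scores)
    the difference is 0 and p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("paired score vectors must share the same cases")
    va10, va01 = _delong_components(scores_a, labels)
    vb10, vb01 = _delong_components(scores_b, labels)
    m, n = va10.size, va01.size
    auc_a, auc_b = va10.mean(), vb10.mean()
    d = float(auc_a - auc_b)

    def _cov(x, y):
        return float(np.cov(x, y, ddof=1)[0, 1]) if x.size > 1 else 0.0

    var_d = (
        (np.var(va10, ddof=1) if m > 1 else 0.0)
        + (np.var(vb10, ddof=1) if m > 1 else 0.0)
        - 2 * _cov(va10, vb10)
    ) / m + (
        (np.var(va01, ddof=1) if n > 1 else 0.0)
        + (np.var(vb01, ddof=1) if n > 1 else 0.0)
        - 2 * _cov(va01, vb01)
    ) / n
    var_d = max(float(var_d), 0.0)
    if var_d == 0.0:
        z = 0.0
        p = 1.0
    else:
        z = d / np.sqrt(var_d)
        p = float(2 * sps.norm.sf(abs(z)))
    return d, var_d, float(z), p


@dataclass
class EquivalenceResult:
    """CI-based equivalence verdict for a paired AUC difference."""

    difference: float
    ci_low: float
    ci_high: float
    margin: float
    equivalent: bool
    p_delong: float
    auc_a: float
    auc_b: float


def equivalence_auc(scores_a, scores_b, labels, margin: float = 0.05) -> EquivalenceResult:
    """Two models are equivalent iff the 95% CI of (AUC_A - AUC_B) lies
    entirely inside the open interval ``(-margin, +margin)``."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    d, var_d, _, p = delong_paired_test(scores_a, scores_b, labels)
    se = np.sqrt(var_d)
    z = sps.norm.ppf(0.975)
    lo, hi = d - z * se, d + z * se
    eq = bool(lo > -margin and hi < margin)
    ra = auc(scores_a, labels)
    rb = auc(scores_b, labels)
    return EquivalenceResult(d, float(lo), float(hi), margin, eq, p, ra.auc, rb.auc)


# ---------------------------------------------------------------------------
# Operating point
# ---------------------------------------------------------------------------

def confusion_at_cutoff(scores, labels, cutoff: float) -> dict:
    """Accuracy / sensitivity / specificity calling positive iff score >= cutoff."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    acc = (tp + tn) / labels.size
    return {
        "cutoff": float(cutoff),
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


def youden_cutoff(scores, labels) -> dict:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores plus
    the two outer extremes; ties in J are broken toward the lowest threshold
    (favouring sensitivity).  Returns the confusion metrics at the optimum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    uniq = np.unique(scores)
    cands = [uniq[0] - 1.0]
    cands.extend(0.5 * (uniq[:-1] + uniq[1:]))
    cands.append(uniq[-1] + 1.0)
    best = None
    for t in cands:
        m = confusion_at_cutoff(scores, labels, t)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, m)
    j, t, m = best
    m["youden_j"] = j
    return m


# ---------------------------------------------------------------------------
# Paired accuracy: exact McNemar
# ---------------------------------------------------------------------------

def mcnemar_exact(correct_a, correct_b) -> float:
    """Exact binomial McNemar p-value on paired correctness indicators.

    With b, c the discordant counts, p = 2 * P(Binom(b+c, 1/2) <= min(b, c)),
    capped at 1; p = 1 when b = c = 0.
    """
    a = np.asarray(correct_a).astype(bool)
    b = np.asarray(correct_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    nb = int(np.sum(a & ~b))
    nc = int(np.sum(~a & b))
    n = nb + nc
    if n == 0:
        return 1.0
    k = min(nb, nc)
    p = 2.0 * sps.binom.cdf(k, n, 0.5)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# ICC (two-way mixed, absolute agreement, single measurement)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """Per-feature ICC between two segmentation sources plus summary stats."""

    icc: np.ndarray
    feature_names: list
    median: float
    iqr: tuple
    form: str = "two-way mixed, absolute agreement, single measurement"


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """ICC(A,1) from an (n_targets, k_raters) table via two-way ANOVA sums.

    (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)); identical columns
    give exactly 1.
    """
    y = np.asarray(ratings, dtype=float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    grand = y.mean()
    row_m = y.mean(axis=1)
    col_m = y.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sst = np.sum((y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        return 1.0 if msr == mse else 0.0
    return float((msr - mse) / denom)


def icc_features(table_a, table_b, feature_names=None) -> ICCResult:
    """Column-wise ICC(A,1) between two aligned feature tables.

    Accepts DataFrames (columns intersected by name must match exactly) or
    plain 2-D arrays of identical shape; rows are lesions.
    """
    import pandas as pd

    if isinstance(table_a, pd.DataFrame) and isinstance(table_b, pd.DataFrame):
        if list(table_a.columns) != list(table_b.columns):
            raise ValueError("feature tables must share identical columns")
        if len(table_a) != len(table_b):
            raise ValueError("feature tables must share identical lesions")
        names = list(table_a.columns)
        A = table_a.to_numpy(dtype=float)
        B = table_b.to_numpy(dtype=float)
    else:
        A = np.asarray(table_a, dtype=float)
        B = np.asarray(table_b, dtype=float)
        if A.shape != B.shape:
            raise ValueError("feature tables must share the same shape")
        names = feature_names or [f"f{i}" for i in range(A.shape[1])]

    # vectorized two-way ANOVA over all columns at once (k = 2 raters)
    n = A.shape[0]
    k = 2
    y = np.stack([A, B], axis=2)  # (n, p, 2)
    grand = y.mean(axis=(0, 2))
    row_m = y.mean(axis=2)
    col_m = y.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2, axis=0)
    ssc = n * np.sum((col_m - grand[:, None]) ** 2, axis=1)
    sst = np.sum((y - grand[None, :, None]) ** 2, axis=(0, 2))
    sse = np.maximum(sst - ssr - ssc, 0.0)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom != 0, (msr - mse) / denom, 1.0)
    icc = np.where(np.isfinite(icc), icc, 1.0)
    q1, q3 = np.percentile(icc, [25, 75])
    return ICCResult(icc, names, float(np.median(icc)), (float(q1), float(q3)))


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple:
    """Mann-Whitney U with two-sided p.

    Exact enumeration for combined n <= 12 without ties; otherwise the
    normal approximation with tie correction.  Returns ``(U_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def normality_test(x, alpha: float = 0.05) -> dict:
    """Shapiro-Wilk (n <= 50) or Lilliefors-style KS screen for normality."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return {"normal": False, "p": np.nan, "test": "none"}
    if x.size <= 50:
        stat, p = sps.shapiro(x)
        name = "shapiro"
    else:
        stat, p = sps.kstest((x - x.mean()) / x.std(ddof=1), "norm")
        name = "ks"
    return {"normal": bool(p > alpha), "p": float(p), "test": name}


# ---------------------------------------------------------------------------
# Hanley-McNeil ROC sample size
# ---------------------------------------------------------------------------

@dataclass
class SampleSizeResult:
    n_pos: int
    n_neg: int
    total: int
    alt_auc: float
    null_auc: float
    alpha: float
    power: float
    allocation_ratio: float


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil binormal-exponential SE of an AUC estimate."""
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def auc_sample_size(
    alt_auc: float,
    allocation_ratio_neg_per_pos: float,
    power: float = 0.80,
    alpha: float = 0.05,
) -> SampleSizeResult:
    """Smallest cohort detecting ``alt_auc`` against a null AUC of 0.5.

    Finds the smallest n_pos such that
    ``z_{alpha/2} * SE0 + z_beta * SE1 <= alt_auc - 0.5`` with
    ``n_neg = max(1, floor(ratio * n_pos))``, SE0 evaluated at AUC 0.5 and SE1
    at the alternative, both by the Hanley-McNeil form.
    """
    if not 0.5 < alt_auc <= 1.0:
        raise ValueError("alternative AUC must lie in (0.5, 1]")
    if allocation_ratio_neg_per_pos <= 0:
        raise ValueError("allocation ratio must be positive")
    z_a = sps.norm.ppf(1 - alpha / 2)
    z_b = sps.norm.ppf(power)
    delta = alt_auc - 0.5
    for n_pos in range(1, 100000):
        n_neg = max(1, int(np.floor(allocation_ratio_neg_per_pos * n_pos)))
        se0 = _hanley_mcneil_se(0.5, n_pos, n_neg)
        se1 = _hanley_mcneil_se(alt_auc, n_pos, n_neg)
        if z_a * se0 + z_b * se1 <= delta:
            return SampleSizeResult(
                n_pos, n_neg, n_pos + n_neg, alt_auc, 0.5, alpha, power,
                allocation_ratio_neg_per_pos,
            )
    raise RuntimeError("sample size search did not converge")
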