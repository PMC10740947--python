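"""Feature standardization and LASSO selection.

Z-score standardization is fitted on the training cohort only (population-SD
convention) and applied unchanged to validation cohorts, so no validation
information leaks into the transform.  Selection runs an L1-penalized
logistic path over a log-spaced lambda grid with stratified cross-validation
and keeps the non-zero-coefficient features at the lambda minimizing the
mean held-out binomial deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Z-score standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    mean: pd.Series
    sd: pd.Series
    dropped: list = field(default_factory=list)

    def checksum(self) -> float:
        return float(self.mean.sum() + self.sd.sum())


def zscore_fit(train: pd.DataFrame) -> StandardizationParams:
    """Per-feature mean/SD from the training table (population SD).

    Zero-variance features are dropped with a warning.
    """
    if len(train) == 0:
        raise ValueError("empty training table")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        log.warning("dropping %d zero-variance features", len(dropped))
    keep = sd.index[sd > 0]
    return StandardizationParams(mean[keep], sd[keep], dropped)


def zscore_apply(params: StandardizationParams, table: pd.DataFrame) -> pd.DataFrame:
    cols = params.mean.index
    return (table[cols] - params.mean) / params.sd


def zscore_invert(params: StandardizationParams, table: pd.DataFrame) -> pd.DataFrame:
    return table * params.sd + params.mean


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------

@dataclass
class LassoResult:
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_sd: np.ndarray
    optimal_lambda: float
    coef: pd.Series
    selected: list
    intercept: float
    folds: int
    seed: int


def _lambda_grid(X: np.ndarray, y: np.ndarray, n: int = 100, decades: float = 4.0):
    """Log grid from lambda_max (all-zero solution) down ``decades``."""
    resid = y - y.mean()
    lam_max = np.max(np.abs(X.T @ resid)) / len(y)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n)


def _fit_l1_logistic(X, y, lam):
    # sklearn parameterizes the penalty as C = 1 / (n * lambda)
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear",
        max_iter=500, tol=1e-6, random_state=0)
    clf.fit(X, y)
    return clf


def lasso_select(X: pd.DataFrame, y, folds: int = 10, seed: int = 0,
                 n_lambdas: int = 100) -> LassoResult:
    """Cross-validated L1-logistic feature selection (minimum criterion).

    ``X`` must already be standardized; ``y`` is binary with the invasive
    class coded 1.  The fold count is capped at the minority class size.
    """
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes required for selection")
    Xv = X.to_numpy(dtype=float)
    lambdas = _lambda_grid(Xv, y, n=n_lambdas)
    folds = int(min(folds, np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xv, y))

    dev = np.empty((len(lambdas), folds))
    for li, lam in enumerate(lambdas):
        for fi, (tr, te) in enumerate(splits):
            clf = _fit_l1_logistic(Xv[tr], y[tr], lam)
            p = np.clip(clf.predict_proba(Xv[te])[:, 1], 1e-12, 1 - 1e-12)
            dev[li, fi] = -2.0 * np.mean(
                y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
    cv_mean = dev.mean(axis=1)
    cv_sd = dev.std(axis=1, ddof=1)
    best = int(np.argmin(cv_mean))
    lam_opt = float(lambdas[best])
    clf = _fit_l1_logistic(Xv, y, lam_opt)
    coef = pd.Series(clf.coef_[0], index=X.columns)
    selected = coef.index[coef != 0].tolist()
    return LassoResult(lambdas, cv_mean, cv_sd, lam_opt, coef, selected,
                       float(clf.intercept_[0]), folds, seed)


def lasso_linear_path(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Linear (squared-error) LASSO coefficients at one penalty.

    Kept alongside the logistic selector because the linear variant has the
    closed-form soft-threshold solution on orthonormal designs, which the
    test suite uses as an oracle.  Objective: 1/(2n) ||y - Xb||^2 + lam |b|.
    """
    model = Lasso(alpha=lam, fit_intercept=True, max_iter=50000, tol=1e-10)
    model.fit(X, y)
    return model.coef_
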