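"""RBF-kernel SVM classification with grid-searched hyperparameters.

The classifier is tuned on the training cohort only, by stratified
cross-validated AUC over a (C, gamma) grid, and refitted on the full
training cohort with Platt sigmoid calibration for probability outputs
(fitted internally on training folds).  Probabilities are monotone in the
decision score, so ROC analyses are unaffected by the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-3, 8))   # 2^-3 .. 2^7
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-9, 2))  # 2^-9 .. 2^1


@dataclass
class ClassifierModel:
    calibrated: CalibratedClassifierCV
    svc: SVC
    feature_names: list
    best_c: float
    best_gamma: float
    cv_auc: float
    grid_scores: pd.DataFrame = field(repr=False)
    folds: int = 10
    seed: int = 0


def svm_train(X: pd.DataFrame, y, c_grid=DEFAULT_C_GRID,
              gamma_grid=DEFAULT_GAMMA_GRID, folds: int = 10,
              seed: int = 0) -> ClassifierModel:
    """Grid-search an RBF-SVM by stratified CV AUC on the training data.

    Ties in CV AUC resolve to the first grid point in (C, gamma) order
    (smallest C, then smallest gamma), favouring the smoother model.
    """
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    folds = int(min(folds, counts.min()))
    Xv = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xv, y))

    rows = []
    best = None
    for c in c_grid:
        for g in gamma_grid:
            aucs = []
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=c, gamma=g)
                clf.fit(Xv[tr], y[tr])
                s = clf.decision_function(Xv[te])
                if np.unique(y[te]).size < 2:
                    continue
                aucs.append(roc_auc_score(y[te], s))
            mean_auc = float(np.mean(aucs)) if aucs else 0.5
            rows.append({"C": c, "gamma": g, "cv_auc": mean_auc})
            if best is None or mean_auc > best[0] + 1e-12:
                best = (mean_auc, c, g)
    cv_auc, c_best, g_best = best
    cal = CalibratedClassifierCV(
        SVC(kernel="rbf", C=c_best, gamma=g_best), method="sigmoid",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        ensemble=False)
    cal.fit(Xv, y)
    svc = cal.calibrated_classifiers_[0].estimator  # refit on full training
    return ClassifierModel(cal, svc, list(X.columns), float(c_best),
                           float(g_best), cv_auc, pd.DataFrame(rows), folds, seed)


def predict_prob(model: ClassifierModel, X: pd.DataFrame) -> np.ndarray:
    """Per-lesion probability of the invasive (positive) class."""
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return model.calibrated.predict_proba(
        X[model.feature_names].to_numpy(dtype=float))[:, 1]


def decision_score(model: ClassifierModel, X: pd.DataFrame) -> np.ndarray:
    """Raw (uncalibrated) SVM decision values, monotone with predict_prob."""
    return model.svc.decision_function(X[model.feature_names].to_numpy(dtype=float))
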