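"""End-to-end study: semi-automatic vs manual segmentation radiomics.

The orchestration follows a statsmodels-like shape: a
:class:`MuscleInvasionStudy` model object is built from a configuration
(or from pre-generated cohorts), its :meth:`~MuscleInvasionStudy.fit` runs
the full pipeline, and the returned :class:`StudyResult` carries the
estimates (AUCs with DeLong CIs, the paired difference and its equivalence
verdict, per-feature ICCs, segmentation overlap metrics), exposes a
``summary()`` table, and can persist all report files.

Pipeline: generate seeded cohorts -> simulated-annotator VOIs -> train the
U-Net segmenter on the training split -> predict masks everywhere ->
extract the radiomics bank from (a) reference masks ("manual" arm) and
(b) predicted masks ("semi-automatic" arm) -> per arm: Z-score + LASSO +
RBF-SVM fitted on the training split only -> score the validation splits
-> ROC/DeLong/equivalence/McNemar/ICC statistics.  The two arms differ
only in the mask supplied to feature extraction; every downstream setting
is shared through this single config object.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .classify import (
    DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, ClassifierModel, predict_prob,
    svm_train,
)
from .phantom import MIBC, PhantomParams, generate_cohort, scaled_counts
from .radiomics import ExtractionConfig, extract_table, feature_matrix
from .seg import (
    SegNetConfig, TrainConfig, assign_vois, predict_lesion, seg_metrics,
    summarize, train_segmenter,
)
from .selection import LassoResult, lasso_select, zscore_apply, zscore_fit

log = logging.getLogger(__name__)

ARMS = ("manual", "semiauto")


@dataclass
class StudyConfig:
    """Everything one study run depends on, hashable for provenance."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    scale: float = 1.0
    net: SegNetConfig = field(default_factory=SegNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    voi_margin: tuple = (1, 5, 5)
    voi_jitter: int = 2
    lasso_folds: int = 10
    svm_folds: int = 10
    c_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    equivalence_margin: float = 0.05
    seed: int = 0

    @classmethod
    def desk_profile(cls, scale: float = 0.25, seed: int = 0,
                     epochs: int = 8) -> "StudyConfig":
        """Small single-CPU profile: 64x64 slices, 8 base channels."""
        return cls(
            scale=scale,
            net=SegNetConfig(input_size=64, depth=4, base_channels=8),
            train=TrainConfig(epochs=epochs, seed=seed),
            voi_margin=(0, 5, 5),  # z-tight box, annotator-style
            voi_jitter=1,
            seed=seed,
        )

    def config_hash(self) -> str:
        def _enc(o):
            if hasattr(o, "to_dict"):
                return o.to_dict()
            if hasattr(o, "__dict__"):
                return {k: _enc(v) for k, v in vars(o).items()}
            if isinstance(o, (tuple, list)):
                return [_enc(v) for v in o]
            return o

        payload = json.dumps(_enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class MuscleInvasionStudy:
    """Model object for the paired two-arm radiomics study.

    Parameters
    ----------
    config
        The shared study configuration.  The global seed drives cohort
        generation, VOI jitter, network training and all CV splits.
    cohorts
        Optional pre-built mapping ``{"train"|"internal"|"external":
        [LesionSample, ...]}``; when omitted, synthetic cohorts are
        generated at the configured scale.
    """

    def __init__(self, config: StudyConfig | None = None, cohorts: dict | None = None):
        self.config = config or StudyConfig()
        self._cohorts = cohorts

    @classmethod
    def from_config(cls, config: StudyConfig) -> "MuscleInvasionStudy":
        return cls(config)

    # -- stages ------------------------------------------------------------
    def _stage_seed(self, k: int) -> np.random.SeedSequence:
        return np.random.SeedSequence((self.config.seed, k))

    def _generate_cohorts(self) -> dict:
        counts = scaled_counts(self.config.scale)
        out = {}
        for i, (tag, (n0, n1)) in enumerate(counts.items()):
            seed = int(self._stage_seed(10 + i).generate_state(1)[0] % (2**31))
            out[tag] = generate_cohort(n0, n1, tag, self.config.phantom, seed)
        return out

    def fit(self, cache_dir=None, progress: bool = False) -> "StudyResult":
        """Run the full study; optionally cache stage outputs.

        With ``cache_dir`` set, completed stages (cohorts, trained
        segmenter, feature tables) are pickled under
        ``<cache_dir>/stages-<confighash>/`` and reloaded on rerun, making
        the pipeline resumable stage by stage.
        """
        cfg = self.config
        cache = None
        if cache_dir is not None:
            cache = Path(cache_dir) / f"stages-{cfg.config_hash()}"
            cache.mkdir(parents=True, exist_ok=True)

        def _cached(name, fn):
            if cache is not None:
                f = cache / f"{name}.pkl"
                if f.exists():
                    log.info("stage %s: reloaded from cache", name)
                    return pickle.loads(f.read_bytes())
            t0 = time.perf_counter()
            val = fn()
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: %.1fs", name, timings[name])
            if cache is not None:
                (cache / f"{name}.pkl").write_bytes(pickle.dumps(val))
            return val

        timings: dict = {}
        cohorts = self._cohorts or _cached("cohorts", self._generate_cohorts)
        all_samples = [s for tag in cohorts for s in cohorts[tag]]

        voi_seed = int(self._stage_seed(20).generate_state(1)[0] % (2**31))
        vois = assign_vois(all_samples, cfg.voi_margin, cfg.voi_jitter, voi_seed)

        segmenter = _cached(
            "segmenter",
            lambda: train_segmenter(cohorts["train"], vois, cfg.net, cfg.train))

        def _predict_all():
            masks, probs = {}, {}
            for s in all_samples:
                pred = predict_lesion(segmenter, s, vois[s.id])
                masks[s.id] = pred.mask
                probs[s.id] = None  # probability volumes are not retained
            return masks

        pred_masks = _cached("pred_masks", _predict_all)

        # segmentation metrics on the validation cohorts
        seg_rows = []
        for tag in ("internal", "external"):
            for s in cohorts[tag]:
                m = seg_metrics(pred_masks[s.id], s.mask)
                seg_rows.append({"id": s.id, "cohort": tag, "dsc": m.dsc,
                                 "recall": m.recall, "precision": m.precision})
        seg_table = pd.DataFrame(seg_rows).set_index("id")

        # lesions whose predicted mask is unusable are dropped from BOTH
        # arms so all paired statistics stay paired
        usable = [s for s in all_samples if pred_masks[s.id].sum() >= 2]
        n_drop = len(all_samples) - len(usable)
        if n_drop:
            log.warning("dropping %d lesions with empty/degenerate "
                        "predicted masks from both arms", n_drop)

        tables = {}
        tables["manual"] = _cached(
            "features_manual",
            lambda: extract_table(usable, None, cfg.extraction, "manual"))
        tables["semiauto"] = _cached(
            "features_semiauto",
            lambda: extract_table(usable, pred_masks, cfg.extraction, "semiauto"))

        # per-arm modelling on the training split only
        t0 = time.perf_counter()
        sel_seed = int(self._stage_seed(30).generate_state(1)[0] % (2**31))
        arm_models, scores_rows = {}, []
        for arm in ARMS:
            tab = tables[arm]
            train_tab = tab[tab.cohort == "train"]
            y_train = (train_tab.label == MIBC).astype(int).to_numpy()
            zp = zscore_fit(feature_matrix(train_tab))
            Xtr = zscore_apply(zp, feature_matrix(train_tab))
            lasso = lasso_select(Xtr, y_train, cfg.lasso_folds, sel_seed)
            selected = lasso.selected or list(
                lasso.coef.abs().sort_values().index[-1:])  # degenerate guard
            clf = svm_train(Xtr[selected], y_train, cfg.c_grid,
                            cfg.gamma_grid, cfg.svm_folds, sel_seed)
            arm_models[arm] = {"zscore": zp, "lasso": lasso, "svm": clf,
                               "selected": selected}
            for tag in ("train", "internal", "external"):
                sub = tab[tab.cohort == tag]
                Xs = zscore_apply(zp, feature_matrix(sub))
                prob = predict_prob(clf, Xs[selected])
                for lid, lab, p in zip(sub.index, sub.label, prob):
                    scores_rows.append({"id": lid, "cohort": tag, "arm": arm,
                                        "label": int(lab == MIBC),
                                        "probability": float(p)})
        timings["modelling"] = time.perf_counter() - t0
        scores = pd.DataFrame(scores_rows)

        # -- statistics ----------------------------------------------------
        performance, equivalence, mcnemar = {}, {}, {}
        cutoffs = {}
        for arm in ARMS:
            tr = scores[(scores.arm == arm) & (scores.cohort == "train")]
            cutoffs[arm] = st.youden_cutoff(tr.probability.to_numpy(),
                                            tr.label.to_numpy())["cutoff"]
        for tag in ("internal", "external"):
            performance[tag] = {}
            sub = {arm: scores[(scores.arm == arm) & (scores.cohort == tag)]
                   .set_index("id") for arm in ARMS}
            common = sub["manual"].index
            labels = sub["manual"].label.to_numpy()
            for arm in ARMS:
                sa = sub[arm].loc[common]
                roc = st.auc(sa.probability.to_numpy(), labels)
                conf = st.confusion_at_cutoff(sa.probability.to_numpy(),
                                              labels, cutoffs[arm])
                se = np.sqrt(roc.variance)
                p_vs_chance = (float(2 * st.sps.norm.sf(abs(roc.auc - 0.5) / se))
                               if se > 0 else 0.0)
                performance[tag][arm] = {
                    "auc": roc.auc, "ci": [roc.ci_low, roc.ci_high],
                    "auc_p_vs_0.5": p_vs_chance,
                    "degenerate_ci": roc.degenerate,
                    **{k: conf[k] for k in
                       ("cutoff", "accuracy", "sensitivity", "specificity")},
                }
            eq = st.equivalence_auc(
                sub["semiauto"].loc[common].probability.to_numpy(),
                sub["manual"].loc[common].probability.to_numpy(),
                labels, cfg.equivalence_margin)
            equivalence[tag] = eq
            corr = {arm: ((sub[arm].loc[common].probability.to_numpy()
                           >= cutoffs[arm]).astype(int) == labels)
                    for arm in ARMS}
            mcnemar[tag] = st.mcnemar_exact(corr["semiauto"], corr["manual"])

        icc = st.icc_features(feature_matrix(tables["manual"]),
                              feature_matrix(tables["semiauto"]))

        return StudyResult(
            config=cfg, cohorts=cohorts, vois=vois, segmenter=segmenter,
            pred_masks=pred_masks, seg_table=seg_table,
            feature_tables=tables, arm_models=arm_models, scores=scores,
            cutoffs=cutoffs, performance=performance, equivalence=equivalence,
            mcnemar_p=mcnemar, icc=icc, timings=timings,
        )


@dataclass
class StudyResult:
    """Fitted study: estimates, uncertainties, diagnostics, reports."""

    config: StudyConfig
    cohorts: dict
    vois: dict
    segmenter: object
    pred_masks: dict
    seg_table: pd.DataFrame
    feature_tables: dict
    arm_models: dict
    scores: pd.DataFrame
    cutoffs: dict
    performance: dict
    equivalence: dict
    mcnemar_p: dict
    icc: st.ICCResult
    timings: dict

    # -- derived views -----------------------------------------------------
    def seg_summary(self) -> dict:
        out = {}
        for tag in ("internal", "external"):
            sub = self.seg_table[self.seg_table.cohort == tag]
            out[tag] = {m: summarize(sub[m]) for m in ("dsc", "recall", "precision")}
        return out

    def selected_features(self, arm: str) -> pd.DataFrame:
        """Selected features with LASSO coefficients and per-cohort
        Mann-Whitney p-values (NMIBC vs MIBC on standardized values)."""
        model = self.arm_models[arm]
        tab = self.feature_tables[arm]
        zp = model["zscore"]
        rows = []
        for name in model["selected"]:
            row = {"feature": name, "coefficient": float(model["lasso"].coef[name])}
            for tag in ("train", "internal", "external"):
                sub = tab[tab.cohort == tag]
                std = zscore_apply(zp, feature_matrix(sub))[name]
                g0 = std[sub.label != MIBC].to_numpy()
                g1 = std[sub.label == MIBC].to_numpy()
                if len(g0) and len(g1):
                    _, p = st.mann_whitney(g0, g1)
                    row[f"p_{tag}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        c = self.config
        lines = [
            "Muscle-invasion radiomics study: semi-automatic vs manual segmentation",
            "=" * 74,
            f"seed {c.seed}  scale {c.scale}  net {c.net.input_size}px/"
            f"{c.net.base_channels}ch  epochs {c.train.epochs}  "
            f"features {c.extraction.n_features}",
            "",
            "Segmentation (semi-automatic vs reference)",
        ]
        for tag, mets in self.seg_summary().items():
            d = mets["dsc"]
            lines.append(f"  {tag:9s} DSC {d['mean']:.3f} +- {d['sd']:.3f} "
                         f"(median {d['median']:.3f}, n={d['n']})")
        lines += ["", "Classification (probability of muscle invasion)"]
        for tag, arms in self.performance.items():
            for arm, m in arms.items():
                lines.append(
                    f"  {tag:9s} {arm:9s} AUC {m['auc']:.3f} "
                    f"({m['ci'][0]:.3f}-{m['ci'][1]:.3f})  acc {m['accuracy']:.3f} "
                    f"sens {m['sensitivity']:.3f} spec {m['specificity']:.3f}")
        lines += ["", f"Equivalence (margin +-{self.config.equivalence_margin})"]
        for tag, eq in self.equivalence.items():
            verdict = "EQUIVALENT" if eq.equivalent else "not equivalent"
            lines.append(
                f"  {tag:9s} dAUC {eq.difference:+.3f} "
                f"({eq.ci_low:+.3f} to {eq.ci_high:+.3f})  {verdict}; "
                f"DeLong p {eq.p_delong:.3f}; McNemar p {self.mcnemar_p[tag]:.3f}")
        lines += [
            "",
            f"Feature agreement: median ICC {self.icc.median:.3f} "
            f"(IQR {self.icc.iqr[0]:.3f}-{self.icc.iqr[1]:.3f}) over "
            f"{len(self.icc.icc)} features",
        ]
        for arm in ARMS:
            sel = self.arm_models[arm]["selected"]
            lines.append(f"  {arm}: {len(sel)} selected features "
                         f"(lambda* {self.arm_models[arm]['lasso'].optimal_lambda:.4f})")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def report_dict(self) -> dict:
        return {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "segmentation": self.seg_summary(),
            "cutoffs": self.cutoffs,
            "performance": self.performance,
            "equivalence": {
                tag: {
                    "difference": eq.difference,
                    "ci": [eq.ci_low, eq.ci_high],
                    "margin": eq.margin,
                    "equivalent": eq.equivalent,
                    "p_delong": eq.p_delong,
                    "auc_semiauto": eq.auc_a,
                    "auc_manual": eq.auc_b,
                    "mcnemar_p": self.mcnemar_p[tag],
                } for tag, eq in self.equivalence.items()
            },
            "icc": {"median": self.icc.median, "iqr": list(self.icc.iqr),
                    "form": self.icc.form},
        }

    def save(self, outdir) -> None:
        """Write the four report files plus scores and run manifest."""
        from .io import save_json

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.seg_table.to_csv(out / "segmentation_metrics.csv")
        for arm in ARMS:
            self.selected_features(arm).to_csv(
                out / f"selected_features_{arm}.csv", index=False)
            self.feature_tables[arm].to_csv(out / f"features_{arm}.csv")
        save_json(self.report_dict(), out / "performance_equivalence.json")
        pd.DataFrame({"feature": self.icc.feature_names,
                      "icc": self.icc.icc}).to_csv(out / "icc.csv", index=False)
        self.scores.to_csv(out / "scores.csv", index=False)
        manifest = {
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "timings_s": {k: round(v, 2) for k, v in self.timings.items()},
            "n_lesions": {t: len(s) for t, s in self.cohorts.items()},
        }
        with open(out / "manifest.jsonl", "a") as fh:
            fh.write(json.dumps(manifest) + "\n")


def run_study(config: StudyConfig, outdir=None, cache_dir=None) -> StudyResult:
    """Functional wrapper: fit the study and optionally save reports."""
    result = MuscleInvasionStudy(config).fit(cache_dir=cache_dir)
    if outdir is not None:
        result.save(outdir)
    return result
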