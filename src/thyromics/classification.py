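"""Thyroid-state classification with nested cross-validated random forests.

Samples are labelled euthyroid (baseline and 8 weeks after treatment stop) or
hyperthyroid (the two treatment visits); the intermediate-recovery visit is
left out, so a complete 16 x 5 design yields 64 labelled samples.  Feature
selection happens in a two-stage (nested) cross-validation: inner resampling
loops train forests on all complete features and accumulate Gini importances
weighted by their test-set ROC AUC; the top-ranked panel is then re-trained on
the outer training set and scored on the untouched outer validation split.
The final reported panel aggregates the AUC-weighted importances over all
inner loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

__all__ = [
    "EUTHYROID",
    "HYPERTHYROID",
    "LABEL_MAP",
    "CVConfig",
    "OuterLoopResult",
    "CVResult",
    "label_samples",
    "complete_feature_filter",
    "roc_auc",
    "weighted_importance",
    "nested_cv",
]

logger = logging.getLogger(__name__)

EUTHYROID = "euthyroid"
HYPERTHYROID = "hyperthyroid"
# bas/w16: normal thyroid state; w4/w8: under levothyroxine; w12: intermediate
LABEL_MAP = {"bas": EUTHYROID, "w16": EUTHYROID,
             "w4": HYPERTHYROID, "w8": HYPERTHYROID, "w12": None}

_MAX_SPLIT_RETRIES = 100


def label_samples(samples: pd.DataFrame, label_map: dict | None = None) -> pd.DataFrame:
    """Assign euthyroid/hyperthyroid labels; intermediate visits are dropped."""
    label_map = LABEL_MAP if label_map is None else label_map
    unknown = sorted(set(samples["time_point"]) - set(label_map))
    if unknown:
        raise ValueError(f"unknown time-point label(s): {', '.join(map(str, unknown))}")
    state = samples["time_point"].map(label_map)
    labeled = samples.loc[state.notna()].copy()
    labeled["state"] = state.loc[state.notna()]
    counts = labeled["state"].value_counts().to_dict()
    logger.info("labeled %d samples for classification: %s", len(labeled), counts)
    return labeled


def complete_feature_filter(matrix: pd.DataFrame, labeled: pd.DataFrame) -> list:
    """Features with zero missing values among the labelled samples."""
    sub = matrix.reindex(labeled.index)
    kept = list(sub.columns[sub.notna().all(axis=0)])
    logger.info("complete-case filter kept %d of %d features", len(kept), matrix.shape[1])
    return kept


def roc_auc(scores, labels, positive=HYPERTHYROID):
    """Empirical ROC curve and trapezoidal AUC.

    Ties in the scores follow the rank/midpoint convention, so the AUC equals
    the pairwise concordance probability with ties counted one half.

    Returns
    -------
    (auc, fpr, tpr)
    """
    y = np.asarray([1 if l == positive else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("ROC requires both classes in the labels")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


def weighted_importance(gini: np.ndarray, aucs) -> np.ndarray:
    """Average importance rows weighted by their loop AUCs: sum(w g) / sum(w)."""
    gini = np.atleast_2d(np.asarray(gini, dtype=float))
    w = np.asarray(aucs, dtype=float)
    if w.ndim != 1 or len(w) != gini.shape[0]:
        raise ValueError("need one AUC per importance row")
    if np.any(w < 0):
        raise ValueError("AUC weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all AUC weights are zero")
    return (w @ gini) / total


@dataclass(frozen=True)
class CVConfig:
    """Settings for the two-stage cross-validation.

    Split fractions default to 2/3 training / 1/3 held out at both stages,
    stratified by class.  ``subject_aware`` keeps all samples of a participant
    on one side of every split (recommended for honest generalization to new
    individuals); the default splits at the sample level.
    """

    n_outer: int = 30
    n_inner: int = 50
    outer_valid_frac: float = 1 / 3
    inner_test_frac: float = 1 / 3
    panel_size: int = 15
    n_trees: int = 500
    max_features: str = "sqrt"
    stratified: bool = True
    subject_aware: bool = False
    seed: int | None = None

    def __post_init__(self):
        for name in ("outer_valid_frac", "inner_test_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly between 0 and 1")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("n_outer and n_inner must be positive")


@dataclass
class OuterLoopResult:
    train_idx: np.ndarray  # positions into the labelled sample array
    valid_idx: np.ndarray
    inner_aucs: np.ndarray  # (n_inner,)
    importance: np.ndarray  # AUC-weighted over this loop's inner fits
    panel: list
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def n_inner_fits(self) -> int:
        return len(self.inner_aucs)


@dataclass
class CVResult:
    feature_ids: list
    outer: list
    mean_auc: float
    importance: pd.Series  # global AUC-weighted aggregate over all inner loops
    panel: list  # final reported panel (global aggregate)

    @property
    def outer_aucs(self) -> np.ndarray:
        return np.array([o.auc for o in self.outer])

    def panel_table(self) -> pd.DataFrame:
        imp = self.importance.loc[self.panel]
        return pd.DataFrame(
            {"rank": np.arange(1, len(self.panel) + 1),
             "feature_id": self.panel,
             "importance": imp.to_numpy()}
        )


def _split(y, groups, frac_held_out, stratified, subject_aware, rng):
    """One train/held-out split; re-drawn by the caller if degenerate."""
    n = len(y)
    if subject_aware:
        uniq = pd.unique(groups)
        k = max(1, min(len(uniq) - 1, int(round(frac_held_out * len(uniq)))))
        held_subj = set(rng.choice(uniq, size=k, replace=False))
        held = np.array([g in held_subj for g in groups])
    elif stratified:
        held = np.zeros(n, dtype=bool)
        for cls in np.unique(y):
            idx = np.nonzero(y == cls)[0]
            k = max(1, min(len(idx) - 1, int(round(frac_held_out * len(idx)))))
            held[rng.choice(idx, size=k, replace=False)] = True
    else:
        k = max(1, min(n - 1, int(round(frac_held_out * n))))
        held = np.zeros(n, dtype=bool)
        held[rng.choice(n, size=k, replace=False)] = True
    return np.nonzero(~held)[0], np.nonzero(held)[0]


def _split_both_classes(y, groups, frac, cfg, rng):
    for attempt in range(_MAX_SPLIT_RETRIES):
        train, held = _split(y, groups, frac, cfg.stratified, cfg.subject_aware, rng)
        if len(np.unique(y[train])) == 2 and len(np.unique(y[held])) == 2:
            if attempt:
                logger.info("re-drew a degenerate split %d time(s)", attempt)
            return train, held
    raise RuntimeError("could not draw a split containing both classes on each side")


def _rank_features(importance: np.ndarray, feature_ids, k: int) -> list:
    order = sorted(range(len(feature_ids)), key=lambda j: (-importance[j], feature_ids[j]))
    return [feature_ids[j] for j in order[:k]]


def nested_cv(matrix: pd.DataFrame, labeled: pd.DataFrame, config: CVConfig) -> CVResult:
    """Two-stage cross-validated random-forest panel selection.

    ``matrix`` must be log-scale and complete over the labelled samples (run
    :func:`complete_feature_filter` first).  Per outer repetition the labelled
    samples are split into training and validation; inner repetitions split
    the outer training set again, train a forest on all features and record
    test-set AUC plus Gini importances.  The AUC-weighted top
    ``panel_size`` features are re-trained on the outer training set and
    scored on the validation split.  Scores are the forest's vote fraction
    for the hyperthyroid class.
    """
    X_all = matrix.reindex(labeled.index).to_numpy(dtype=float)
    if np.isnan(X_all).any():
        raise ValueError("classification matrix contains missing values; "
                         "apply complete_feature_filter first")
    feature_ids = list(matrix.columns)
    if config.panel_size > len(feature_ids):
        raise ValueError(
            f"panel_size {config.panel_size} exceeds available features {len(feature_ids)}"
        )
    y = (labeled["state"] == HYPERTHYROID).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for classification")
    groups = labeled["subject_id"].to_numpy()
    rng = np.random.default_rng(config.seed)

    def _forest():
        return RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.max_features,
            random_state=int(rng.integers(2**31 - 1)),
        )

    outer_results = []
    all_gini, all_w = [], []
    for _ in range(config.n_outer):
        tr, va = _split_both_classes(y, groups, config.outer_valid_frac, config, rng)
        inner_aucs = np.empty(config.n_inner)
        inner_gini = np.empty((config.n_inner, len(feature_ids)))
        for i in range(config.n_inner):
            itr, ite = _split_both_classes(
                y[tr], groups[tr], config.inner_test_frac, config, rng
            )
            rf = _forest().fit(X_all[tr][itr], y[tr][itr])
            scores = rf.predict_proba(X_all[tr][ite])[:, list(rf.classes_).index(1)]
            fpr, tpr, _ = roc_curve(y[tr][ite], scores)
            inner_aucs[i] = np.trapezoid(tpr, fpr)
            inner_gini[i] = rf.feature_importances_
        loop_imp = weighted_importance(inner_gini, inner_aucs)
        panel = _rank_features(loop_imp, feature_ids, config.panel_size)
        cols = [feature_ids.index(f) for f in panel]
        rf = _forest().fit(X_all[tr][:, cols], y[tr])
        scores = rf.predict_proba(X_all[va][:, cols])[:, list(rf.classes_).index(1)]
        fpr, tpr, _ = roc_curve(y[va], scores)
        auc = float(np.trapezoid(tpr, fpr))
        outer_results.append(
            OuterLoopResult(train_idx=tr, valid_idx=va, inner_aucs=inner_aucs,
                            importance=loop_imp, panel=panel, auc=auc,
                            fpr=fpr, tpr=tpr)
        )
        all_gini.append(inner_gini)
        all_w.append(inner_aucs)

    global_imp = weighted_importance(np.vstack(all_gini), np.concatenate(all_w))
    final_panel = _rank_features(global_imp, feature_ids, config.panel_size)
    mean_auc = float(np.mean([o.auc for o in outer_results]))
    logger.info("nested CV: mean outer AUC %.3f over %d loops", mean_auc, config.n_outer)
    return CVResult(
        feature_ids=feature_ids,
        outer=outer_results,
        mean_auc=mean_auc,
        importance=pd.Series(global_imp, index=feature_ids),
        panel=final_panel,
    )
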