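"""Recursive-feature-elimination random forest with repeated nested CV.

The engine mirrors a caret-style nested design: ``repeats`` × ``outer``-fold
cross-validation, and within each outer training fold an inner 5-fold CV in
which features are ranked by Gini impurity importance and candidate subset
sizes are evaluated.  Each inner fold's best subset increments a per-feature
selection-frequency table; with the printed configuration (10 repeats × 5
outer × 5 inner) the table spans exactly 250 analysis folds, and a feature
is *relevant* when selected in strictly more than 10% of them (> 25 / 250).

The final model is refit on the full discovery set at the modal best subset
size across outer folds (ties break toward the smaller size, for parsimony).
Cross-validated AUROC is computed from pooled outer-fold held-out
predictions (per-sample scores averaged over repeats).  Class imbalance is
handled with stratified folds plus inverse-frequency class weights — no
resampling at the forest stage.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .evaluate import auroc
from .imaging import ValidationError

logger = logging.getLogger("rimradiomics")

__all__ = [
    "RFEConfig",
    "SelectionFrequencyTable",
    "FittedModel",
    "rfe_rf_train",
    "relevant_features",
    "predict_scores",
]


@dataclass
class RFEConfig:
    """Nested-CV configuration; defaults follow the printed design."""

    n_trees: int = 2000
    outer_folds: int = 5
    repeats: int = 10
    inner_folds: int = 5
    subset_sizes: tuple[int, ...] | None = None   # None -> {2,4,8,16,32,all}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")

    @property
    def total_analysis_folds(self) -> int:
        return self.repeats * self.outer_folds * self.inner_folds

    def candidate_sizes(self, n_features: int) -> list[int]:
        sizes = self.subset_sizes or (2, 4, 8, 16, 32)
        out = sorted({s for s in sizes if s < n_features} | {n_features})
        return out


@dataclass
class SelectionFrequencyTable:
    """How often each feature appeared in an analysis fold's best subset."""

    counts: dict[str, int]
    total: int

    def fraction(self, feature: str) -> float:
        return self.counts.get(feature, 0) / self.total


@dataclass
class FittedModel:
    forest: RandomForestClassifier
    selected_features: list[str]
    best_size: int
    cv_auroc: float
    frequencies: SelectionFrequencyTable
    outer_sizes: list[int] = field(default_factory=list)
    classes: tuple = (0, 1)
    cv_scores: np.ndarray | None = None   # pooled outer-fold held-out scores
    cv_labels: np.ndarray | None = None


def _make_forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, class_weight="balanced",
        random_state=seed, n_jobs=1)


def _rank_features(X: np.ndarray, y: np.ndarray, n_trees: int,
                   seed: int) -> np.ndarray:
    """Feature indices ordered by decreasing Gini importance."""
    forest = _make_forest(n_trees, seed).fit(X, y)
    imp = forest.feature_importances_
    # stable tie-break by original column order
    return np.argsort(-imp, kind="stable")


def _stratified_splits(y: np.ndarray, k: int, rng: np.random.Generator):
    """Stratified k-fold splits whose training sides contain both classes.

    Re-draws with a fresh seed when a degenerate fold appears (possible only
    for tiny minorities); unresolvable after 10 attempts raises.
    """
    for _ in range(10):
        skf = StratifiedKFold(k, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splits = list(skf.split(np.zeros((len(y), 1)), y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[va])) == 2
               for tr, va in splits):
            return splits
    raise ValidationError("could not build stratified folds with both classes")


def rfe_rf_train(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    config: RFEConfig | None = None,
) -> FittedModel:
    """Train the nested RFE-RF classifier on a standardized discovery table.

    See the module docstring for the fold bookkeeping; all randomness is
    derived deterministically from ``config.seed``.
    """
    config = config or RFEConfig()
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("binary labels with both classes required")
    if counts.min() < 10:
        warnings.warn(f"minority class has only {counts.min()} samples",
                      stacklevel=2)
    cols = list(table.columns)
    X = table.to_numpy(dtype=float)
    n = len(y)
    sizes = config.candidate_sizes(len(cols))
    rng = np.random.default_rng(config.seed)

    freq: Counter[str] = Counter()
    outer_best_sizes: list[int] = []
    score_sum = np.zeros(n)
    score_cnt = np.zeros(n)

    for rep in range(config.repeats):
        for otr, ote in _stratified_splits(y, config.outer_folds, rng):
            Xo, yo = X[otr], y[otr]
            size_aucs = {s: [] for s in sizes}
            for itr, iva in _stratified_splits(yo, config.inner_folds, rng):
                fit_seed = int(rng.integers(2 ** 31 - 1))
                ranker = _make_forest(config.n_trees, fit_seed)
                ranker.fit(Xo[itr], yo[itr])
                order = np.argsort(-ranker.feature_importances_, kind="stable")
                best_auc, best_subset, best_s = -np.inf, None, None
                for s in sizes:
                    if s == len(cols):
                        sub = np.arange(len(cols))
                        forest = ranker   # full set: the ranking fit itself
                    else:
                        sub = order[:s]
                        forest = _make_forest(config.n_trees, fit_seed)
                        forest.fit(Xo[itr][:, sub], yo[itr])
                    pos = list(forest.classes_).index(1)
                    sc = forest.predict_proba(Xo[iva][:, sub])[:, pos]
                    auc = auroc(sc, yo[iva])
                    size_aucs[s].append(auc)
                    # smaller size wins ties (strict >): parsimony
                    if auc > best_auc:
                        best_auc, best_subset, best_s = auc, sub, s
                for j in best_subset:
                    freq[cols[j]] += 1
            mean_inner = {s: np.mean(v) for s, v in size_aucs.items()}
            best_size_outer = min(
                (s for s in sizes
                 if mean_inner[s] == max(mean_inner.values())))
            outer_best_sizes.append(best_size_outer)
            # outer-fold held-out predictions at this fold's best size
            fit_seed = int(rng.integers(2 ** 31 - 1))
            order = _rank_features(Xo, yo, config.n_trees, fit_seed)
            sub = order[:best_size_outer]
            forest = _make_forest(config.n_trees, fit_seed).fit(Xo[:, sub], yo)
            pos = list(forest.classes_).index(1)
            score_sum[ote] += forest.predict_proba(X[ote][:, sub])[:, pos]
            score_cnt[ote] += 1

    freq_table = SelectionFrequencyTable(
        {c: freq.get(c, 0) for c in cols}, config.total_analysis_folds)
    size_counts = Counter(outer_best_sizes)
    top = max(size_counts.values())
    modal_size = min(s for s, c in size_counts.items() if c == top)

    cv_scores = score_sum / np.maximum(score_cnt, 1)
    cv_auc = auroc(cv_scores, y)

    final_seed = int(rng.integers(2 ** 31 - 1))
    order = _rank_features(X, y, config.n_trees, final_seed)
    sub = order[:modal_size]
    forest = _make_forest(config.n_trees, final_seed).fit(X[:, sub], y)
    selected = [cols[j] for j in sub]
    logger.info("RFE-RF: modal size %d, CV AUROC %.3f", modal_size, cv_auc)
    return FittedModel(
        forest=forest, selected_features=selected, best_size=modal_size,
        cv_auroc=float(cv_auc), frequencies=freq_table,
        outer_sizes=outer_best_sizes, classes=tuple(forest.classes_),
        cv_scores=cv_scores, cv_labels=y.copy())


def relevant_features(
    freqs: SelectionFrequencyTable,
    threshold_fraction: float = 0.10,
) -> set[str]:
    """Features selected in strictly more than ``threshold_fraction`` of the
    analysis folds (> 25 of 250 in the printed configuration)."""
    cut = threshold_fraction * freqs.total
    return {f for f, c in freqs.counts.items() if c > cut}


def predict_scores(
    model: FittedModel,
    table: pd.DataFrame,
) -> np.ndarray:
    """Positive-class vote fractions for held-out lesions."""
    missing = [c for c in model.selected_features if c not in table.columns]
    if missing:
        raise ValidationError(f"missing selected feature columns: {missing}")
    X = table[model.selected_features].to_numpy(dtype=float)
    pos = list(model.forest.classes_).index(1)
    return model.forest.predict_proba(X)[:, pos]
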