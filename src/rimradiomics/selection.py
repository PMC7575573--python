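"""Three-stage dimensionality-reduction cascade and z-score standardization.

Applied, on the discovery cohort only, in the fixed order:

1. **stability filter** — Kruskal–Wallis test of each radiomic feature across
   CT-scanner-manufacturer groups; features varying significantly
   (p < alpha, default 0.05 uncorrected) are deemed scanner-unstable and
   removed;
2. **mRMR** — greedy maximum-relevance/minimum-redundancy ranking (difference
   form, mutual information on 3-bin equal-frequency discretizations),
   keeping the top ``ceil(fraction * n)`` features (default 80%);
3. **elastic-net prefilter** — an elastic-net-penalized logistic model tuned
   by repeated stratified 5-fold cross-validation (10 repetitions) with
   minority-class upsampling inside training folds; features whose mean
   absolute standardized coefficient is nonzero survive.

Clinical covariates bypass the cascade and are appended before
classification.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .imaging import ValidationError

logger = logging.getLogger("rimradiomics")

__all__ = [
    "SelectionStage",
    "SelectionReport",
    "stability_filter",
    "mrmr_select",
    "prefilter_elastic_net",
    "zscore_standardize",
    "run_cascade",
]


@dataclass
class SelectionStage:
    name: str
    n_in: int
    n_out: int
    scores: dict[str, float]        # per-feature score (meaning is stage-specific)
    selected: list[str]


@dataclass
class SelectionReport:
    """Per-stage record of the cascade; `selected` is the final survivor list."""

    stages: list[SelectionStage] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.stages[-1].selected) if self.stages else []

    def to_dict(self) -> dict:
        return {
            s.name: {
                "n_in": s.n_in, "n_out": s.n_out,
                "scores": s.scores, "selected": s.selected,
            } for s in self.stages
        }


# ---------------------------------------------------------------------------
# Stage 1: scanner-stability filter
# ---------------------------------------------------------------------------

def stability_filter(
    features: pd.DataFrame,
    scanner: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> SelectionStage:
    """Remove features varying significantly across scanner manufacturers.

    Kruskal–Wallis across manufacturer groups; a feature with p < alpha is
    scanner-unstable and dropped.  With fewer than two groups of >= 3 lesions
    the filter is skipped (all features retained).  Constant features are
    retained with p = 1 (no variation to test).
    """
    scanner = np.asarray(scanner)
    groups, counts = np.unique(scanner, return_counts=True)
    usable = groups[counts >= 3]
    pvals: dict[str, float] = {}
    if len(usable) < 2:
        warnings.warn("fewer than 2 scanner groups with >= 3 lesions; "
                      "stability filter skipped", stacklevel=2)
        selected = list(features.columns)
        return SelectionStage("stability", len(selected), len(selected),
                              {c: 1.0 for c in features.columns}, selected)
    selected = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        samples = [x[scanner == g] for g in usable]
        if np.all(x == x[0]):
            logger.info("constant feature %s retained by stability filter", col)
            p = 1.0
        else:
            try:
                p = float(stats.kruskal(*samples).pvalue)
            except ValueError:   # all values identical within the test
                p = 1.0
        pvals[col] = p
        if p >= alpha:
            selected.append(col)
    return SelectionStage("stability", features.shape[1], len(selected),
                          pvals, selected)


# ---------------------------------------------------------------------------
# Stage 2: mRMR
# ---------------------------------------------------------------------------

def _equal_frequency_bins(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return np.ceil(ranks * n_bins / len(x)).astype(int)


def _mi_discrete(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    """Mutual information (nats) of two small-alphabet integer arrays.

    Equivalent to sklearn's ``mutual_info_score`` but without its per-call
    overhead; the greedy mRMR loop evaluates O(n_features^2) pairs.
    """
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(ka, kb).sum(axis=1)
    pb = joint.reshape(ka, kb).sum(axis=0)
    outer = np.outer(pa, pb).ravel()
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def mrmr_select(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    fraction: float = 0.8,
    n_bins: int = 3,
) -> SelectionStage:
    """Greedy maximum-relevance minimum-redundancy ranking (difference form).

    Score of a candidate f given selected set S:
    ``MI(f; y) - mean_{s in S} MI(f; s)``, with mutual information computed
    on equal-frequency 3-bin discretizations.  Returns the top
    ``ceil(fraction * n)`` features in rank order; ties break by feature-id
    lexicographic order.
    """
    if not 0 < fraction <= 1:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    cols = list(features.columns)
    if len(cols) < 2:
        raise ValidationError("mRMR requires >= 2 candidate features")
    binned = {c: _equal_frequency_bins(features[c].to_numpy(dtype=float), n_bins) - 1
              for c in cols}
    y01 = (y == np.unique(y)[1]).astype(int)
    relevance = {c: _mi_discrete(binned[c], y01, n_bins, 2) for c in cols}
    n_keep = math.ceil(fraction * len(cols))

    selected: list[str] = []
    scores: dict[str, float] = {}
    redundancy_sum = {c: 0.0 for c in cols}
    remaining = sorted(cols)
    while len(selected) < n_keep:
        best, best_score = None, -np.inf
        for c in remaining:   # lexicographic order makes ties deterministic
            red = redundancy_sum[c] / len(selected) if selected else 0.0
            sc = relevance[c] - red
            if sc > best_score:
                best, best_score = c, sc
        selected.append(best)
        scores[best] = float(best_score)
        remaining.remove(best)
        for c in remaining:
            redundancy_sum[c] += _mi_discrete(binned[c], binned[best],
                                              n_bins, n_bins)
    return SelectionStage("mrmr", len(cols), len(selected), scores, selected)


# ---------------------------------------------------------------------------
# Stage 3: elastic-net prefilter
# ---------------------------------------------------------------------------

def _upsample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Upsample the minority class with replacement to balance counts."""
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    idx_all = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt < n_max:
            extra = rng.choice(idx, size=n_max - cnt, replace=True)
            idx = np.concatenate([idx, extra])
        idx_all.append(idx)
    idx_all = np.concatenate(idx_all)
    return X[idx_all], y[idx_all]


def prefilter_elastic_net(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    folds: int = 5,
    repeats: int = 10,
    upsample: bool = True,
    l1_ratios: tuple[float, ...] = (0.5, 0.9),
    Cs: tuple[float, ...] = (0.1, 1.0),
    seed: int = 0,
) -> SelectionStage:
    """Elastic-net-penalized logistic prefilter.

    Hyperparameters (mixing ``l1_ratio`` and inverse strength ``C``) are
    tuned by repeated stratified `folds`-fold CV (x `repeats`) maximizing
    mean validation AUROC, with the minority class upsampled with replacement
    inside training folds only.  Importance is the mean absolute coefficient
    (on z-scored features) of per-repeat refits at the selected
    hyperparameters; features with importance > 0 survive.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    cols = list(features.columns)
    X = features.to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    rng = np.random.default_rng(seed)

    def _fit(Xtr, ytr, l1, C):
        model = LogisticRegression(
            penalty="elasticnet", solver="saga", l1_ratio=l1, C=C,
            max_iter=2000, tol=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(Xtr, ytr)
            except Exception:
                logger.warning("elastic-net fit failed; strongest-penalty fallback")
                model = LogisticRegression(
                    penalty="elasticnet", solver="saga", l1_ratio=1.0,
                    C=min(Cs), max_iter=5000)
                model.fit(Xtr, ytr)
        return model

    grid = [(l1, C) for l1 in l1_ratios for C in Cs]
    cv_scores = {g: [] for g in grid}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2 ** 31 - 1)))
        for tr, va in skf.split(Xz, y):
            Xtr, ytr = Xz[tr], y[tr]
            if upsample:
                Xtr, ytr = _upsample(Xtr, ytr, rng)
            for g in grid:
                m = _fit(Xtr, ytr, *g)
                s = m.decision_function(Xz[va])
                cv_scores[g].append(roc_auc_score(y[va], s))
    mean_auc = {g: float(np.mean(v)) for g, v in cv_scores.items()}
    best = max(grid, key=lambda g: (mean_auc[g], -g[1]))   # prefer stronger penalty on ties

    coefs = []
    for rep in range(repeats):
        Xtr, ytr = (Xz, y) if not upsample else _upsample(Xz, y, rng)
        coefs.append(np.abs(_fit(Xtr, ytr, *best).coef_.ravel()))
    importance = np.mean(coefs, axis=0)
    scores = {c: float(v) for c, v in zip(cols, importance)}
    selected = [c for c, v in zip(cols, importance) if v > 0]
    stage = SelectionStage("elastic_net", len(cols), len(selected), scores,
                           selected)
    stage.scores["_best_l1_ratio"] = float(best[0])
    stage.scores["_best_C"] = float(best[1])
    return stage


# ---------------------------------------------------------------------------
# z-score standardization
# ---------------------------------------------------------------------------

def zscore_standardize(
    train: pd.DataFrame,
    apply_to: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, dict]:
    """Center/scale columns to mean 0, sd 1 (sample sd, ddof=1) on `train`;
    transform `apply_to` with the training parameters only.

    Zero-variance training columns pass through as all-zeros with a warning.
    """
    if apply_to is not None and list(apply_to.columns) != list(train.columns):
        raise ValidationError("column sets of train and apply_to differ")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} constant column(s) standardized to 0",
                      stacklevel=2)
        sd = sd.mask(zero, 1.0)
    params = {"mean": mu.to_dict(), "sd": sd.to_dict()}
    train_z = (train - mu) / sd
    out = None if apply_to is None else (apply_to - mu) / sd
    return train_z, out, params


def run_cascade(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    scanner: np.ndarray | pd.Series,
    alpha: float = 0.05,
    mrmr_fraction: float = 0.8,
    prefilter_kwargs: dict | None = None,
    seed: int = 0,
) -> SelectionReport:
    """Run stability -> mRMR -> elastic-net on a discovery feature table."""
    report = SelectionReport()
    s1 = stability_filter(features, scanner, alpha)
    report.stages.append(s1)
    s2 = mrmr_select(features[s1.selected], labels, mrmr_fraction)
    report.stages.append(s2)
    kwargs = dict(prefilter_kwargs or {})
    kwargs.setdefault("seed", seed)
    s3 = prefilter_elastic_net(features[s2.selected], labels, **kwargs)
    report.stages.append(s3)
    return report
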