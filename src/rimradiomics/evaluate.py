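"""Performance and association statistics.

* AUROC in its Mann–Whitney form (fraction of positive–negative score pairs
  correctly ordered, ties counted 0.5);
* DeLong placement-value variance, Wald 95% CIs, and the unpaired two-sample
  DeLong z-test for comparing AUROCs from disjoint cohorts (training CV vs
  held-out test);
* sensitivity / specificity / PPV / NPV with exact Clopper–Pearson 95% CIs;
* per-feature two-sided Mann–Whitney U tests with Benjamini–Hochberg
  adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .imaging import ValidationError

logger = logging.getLogger("rimradiomics")

__all__ = [
    "EvaluationReport",
    "auroc",
    "delong_variance",
    "delong_ci",
    "delong_ci_and_test",
    "confusion_metrics",
    "mannwhitney_bh",
    "roc_coordinates",
    "format_report",
]


@dataclass
class EvaluationReport:
    """Everything reported for one classification task."""

    task: str
    n_discovery: int
    n_validation: int
    cv_auroc: float
    test_auroc: float
    test_auroc_ci: tuple[float, float]
    delong_p: float
    metrics: dict[str, tuple[float, float, float]]  # name -> (point, lo, hi)
    feature_associations: pd.DataFrame | None = None
    selected_features: list[str] = field(default_factory=list)
    relevant_features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "task": self.task,
            "n_discovery": self.n_discovery,
            "n_validation": self.n_validation,
            "cv_auroc": self.cv_auroc,
            "test_auroc": self.test_auroc,
            "test_auroc_ci": list(self.test_auroc_ci),
            "delong_p": self.delong_p,
            "metrics": {k: list(v) for k, v in self.metrics.items()},
            "selected_features": self.selected_features,
            "relevant_features": self.relevant_features,
        }
        if self.feature_associations is not None:
            d["feature_associations"] = self.feature_associations.to_dict(
                orient="list")
        return d


# ---------------------------------------------------------------------------
# AUROC and DeLong machinery
# ---------------------------------------------------------------------------

def _split_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("AUROC undefined: one class absent")
    return pos, neg


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos, neg = _split_scores(scores, labels)
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    v10 = ((pos[:, None] > neg[None, :]).sum(axis=1)
           + 0.5 * (pos[:, None] == neg[None, :]).sum(axis=1)) / len(neg)
    v01 = ((pos[None, :] > neg[:, None]).sum(axis=1)
           + 0.5 * (pos[None, :] == neg[:, None]).sum(axis=1)) / len(pos)
    return v10, v01


def delong_variance(scores, labels) -> float:
    """Variance of the empirical AUROC from the covariance of placements."""
    pos, neg = _split_scores(scores, labels)
    v10, v01 = _placements(pos, neg)
    s10 = np.var(v10, ddof=1) if len(pos) > 1 else 0.0
    s01 = np.var(v01, ddof=1) if len(neg) > 1 else 0.0
    return float(s10 / len(pos) + s01 / len(neg))


def delong_ci(scores, labels, level: float = 0.95):
    """(AUROC, (lo, hi)) with a Wald interval truncated to [0, 1]."""
    a = auroc(scores, labels)
    var = delong_variance(scores, labels)
    if var == 0:
        warnings.warn("degenerate DeLong variance; CI clamped", stacklevel=2)
        return a, (a, a)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return a, (max(0.0, a - half), min(1.0, a + half))


def delong_ci_and_test(scores_a, labels_a, scores_b, labels_b):
    """Unpaired DeLong comparison of two AUROCs from independent cohorts.

    Returns ``((auc_a, ci_a), (auc_b, ci_b), p)`` where p is the two-sided
    z-test on the AUROC difference with summed placement variances.  When
    both variances are degenerate (AUROC exactly 0 or 1) the p-value is NaN
    unless the difference is exactly 0, which yields p = 1.0.
    """
    auc_a, ci_a = delong_ci(scores_a, labels_a)
    auc_b, ci_b = delong_ci(scores_b, labels_b)
    var = delong_variance(scores_a, labels_a) + delong_variance(scores_b, labels_b)
    diff = auc_a - auc_b
    if diff == 0:
        p = 1.0
    elif var == 0:
        warnings.warn("degenerate DeLong variance; p set to NaN", stacklevel=2)
        p = float("nan")
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return (auc_a, ci_a), (auc_b, ci_b), p


# ---------------------------------------------------------------------------
# Confusion metrics
# ---------------------------------------------------------------------------

def confusion_metrics(predicted, truth, level: float = 0.95) -> dict:
    """Sensitivity/specificity/PPV/NPV with Clopper–Pearson exact CIs.

    Metrics with an empty denominator are NaN with a warning.
    Returns ``{name: (point, ci_lo, ci_hi)}``.
    """
    yhat = np.asarray(predicted).astype(int)
    y = np.asarray(truth).astype(int)
    if yhat.shape != y.shape:
        raise ValidationError("prediction/truth length mismatch")
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    out = {}
    for name, num, den in (
        ("sensitivity", tp, tp + fn),
        ("specificity", tn, tn + fp),
        ("ppv", tp, tp + fp),
        ("npv", tn, tn + fn),
    ):
        if den == 0:
            warnings.warn(f"{name} undefined (empty denominator)", stacklevel=2)
            out[name] = (float("nan"), float("nan"), float("nan"))
            continue
        lo, hi = proportion_confint(num, den, alpha=1 - level, method="beta")
        out[name] = (num / den, float(lo), float(hi))
    return out


# ---------------------------------------------------------------------------
# Feature associations
# ---------------------------------------------------------------------------

def mannwhitney_bh(
    features: pd.DataFrame,
    labels,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per feature with BH adjustment.

    Exact enumeration when both groups have < 8 samples and no ties;
    normal approximation with tie correction otherwise.  Constant features
    get p = 1 by convention.
    """
    y = np.asarray(labels).astype(int)
    if features.shape[1] < 1:
        raise ValidationError("need at least one feature")
    if (y == 1).sum() < 1 or (y == 0).sum() < 1:
        raise ValidationError("both classes required")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        a, b = x[y == 1], x[y == 0]
        if np.all(x == x[0]):
            logger.info("constant feature %s: p set to 1", col)
            rows.append((col, len(a) * len(b) / 2.0, 1.0))
            continue
        exact = (len(a) < 8 and len(b) < 8
                 and len(np.unique(x)) == len(x))
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic")
        rows.append((col, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["feature", "U", "p"])
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Reporting helpers
# ---------------------------------------------------------------------------

def roc_coordinates(scores, labels) -> pd.DataFrame:
    """ROC curve coordinates (threshold, sensitivity, 1-specificity)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int),
                              np.asarray(scores, dtype=float))
    return pd.DataFrame({"threshold": thr, "sensitivity": tpr,
                         "one_minus_specificity": fpr})


def format_report(report: EvaluationReport) -> str:
    """Human-readable performance table for one task."""
    lines = [
        f"Task: {report.task}   discovery n={report.n_discovery}   "
        f"validation n={report.n_validation}",
        f"{'':14s}{'AUROC (95% CI)':>24s}",
        f"{'training CV':14s}{report.cv_auroc:>10.2f}{'':14s}",
        f"{'test':14s}{report.test_auroc:>10.2f} "
        f"({report.test_auroc_ci[0]:.2f}, {report.test_auroc_ci[1]:.2f})",
        f"DeLong train-CV vs test p = {report.delong_p:.2f}",
        "",
    ]
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        point, lo, hi = report.metrics[name]
        lines.append(f"{name:12s} {point:5.2f} ({lo:.2f}, {hi:.2f})")
    if report.relevant_features:
        lines.append("")
        lines.append("relevant features (> 10% of analysis folds):")
        for f in report.relevant_features:
            lines.append(f"  {f}")
    return "\n".join(lines) + "\n"
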