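"""End-to-end orchestration of the two classification tasks.

Stages, in order: simulate (or ingest) → resample to the isotropic 1 mm grid
→ rim construction → feature extraction → stratified 70/30 split → label
derivation → selection cascade (discovery only) → z-score standardization
(training parameters only) → nested RFE-RF training → held-out prediction →
evaluation.  Every stochastic stage consumes a seed derived deterministically
from the pipeline seed, so a (config, seed) pair reproduces the run exactly.

Tasks:

* ``mmr`` — MMR-D (positive) vs CN-low-like ∪ CN-high-like; POLE-subtype
  lesions are excluded;
* ``tmb`` — TMB-high (TMB strictly > 15.5 mut/Mb, positive) vs TMB-low, all
  subtypes included.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import classify, evaluate, features as feat, imaging, selection, synthetic
from .imaging import ValidationError

logger = logging.getLogger("rimradiomics")

__all__ = [
    "PipelineConfig",
    "TaskDefinition",
    "TASKS",
    "split_cohort",
    "derive_labels",
    "encode_clinical",
    "extract_cohort_features",
    "load_cohort",
    "run_pipeline",
]

CLINICAL_COLUMNS = ("age", "histology", "grade", "stage", "scanner")
LABEL_COLUMNS = ("subtype", "tmb")


@dataclass
class TaskDefinition:
    name: str
    positive: str                   # description of the positive class
    excluded_subtypes: tuple[str, ...] = ()


TASKS = {
    "mmr": TaskDefinition("mmr", positive="MMR-D",
                          excluded_subtypes=("POLE",)),
    "tmb": TaskDefinition("tmb", positive=f"TMB > {synthetic.TMB_CUTPOINT}"),
}


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    task: str = "mmr"
    split_fraction: float = 0.70
    tmb_cutpoint: float = synthetic.TMB_CUTPOINT
    margin_mm: float = 3.0
    n_bins: int = 32
    rfe: classify.RFEConfig = field(default_factory=classify.RFEConfig)
    selection_alpha: float = 0.05
    mrmr_fraction: float = 0.8
    prefilter: dict = field(default_factory=dict)
    simulation: synthetic.SimulationConfig | None = None
    data_dir: str | None = None
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split fraction must be in (0, 1)")
        if self.tmb_cutpoint <= 0:
            raise ValidationError("TMB cut-point must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "rfe" in raw:
            raw["rfe"] = classify.RFEConfig(**raw["rfe"])
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = synthetic.SimulationConfig(**raw["simulation"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Split and labels
# ---------------------------------------------------------------------------

def split_cohort(
    n: int | pd.DataFrame,
    fraction: float = 0.70,
    stratify_on=None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split into discovery/validation index arrays.

    Sizes are exactly ``(round(fraction * n), n - round(fraction * n))``.
    `stratify_on` is a per-row stratum label array (e.g. subtype x task
    label); within each stratum the discovery quota follows largest-remainder
    rounding so the global sizes are honoured.  A stratum of size 1 goes to
    discovery with a warning.
    """
    if isinstance(n, pd.DataFrame):
        n = len(n)
    if n < 2:
        raise ValidationError("need at least 2 lesions to split")
    if not 0 < fraction < 1:
        raise ValidationError(f"split fraction must be in (0, 1), got {fraction}")
    n_disc = int(math.floor(fraction * n + 0.5))
    strata = (np.zeros(n, dtype=object) if stratify_on is None
              else np.asarray(stratify_on, dtype=object))
    if len(strata) != n:
        raise ValidationError("stratify_on length mismatch")
    rng = np.random.default_rng(seed)

    labels = sorted(set(strata), key=str)
    idx_by = {s: rng.permutation(np.flatnonzero(strata == s)) for s in labels}
    quota = {}
    forced = 0
    for s in labels:
        if len(idx_by[s]) == 1:
            warnings.warn(f"stratum {s!r} has a single lesion; "
                          "assigned to discovery", stacklevel=2)
            quota[s] = 1
            forced += 1
    free = [s for s in labels if s not in quota]
    remaining = n_disc - forced
    base = {s: min(int(math.floor(fraction * len(idx_by[s]))), len(idx_by[s]))
            for s in free}
    remaining -= sum(base.values())
    frac_part = sorted(
        free, key=lambda s: (-(fraction * len(idx_by[s]) - base[s]), str(s)))
    i = 0
    while remaining > 0 and free:
        s = frac_part[i % len(frac_part)]
        if base[s] < len(idx_by[s]):
            base[s] += 1
            remaining -= 1
        i += 1
    while remaining < 0:
        s = frac_part[(i - 1) % len(frac_part)]
        if base[s] > 0:
            base[s] -= 1
            remaining += 1
        i -= 1
    quota.update(base)

    disc, val = [], []
    for s in labels:
        k = quota[s]
        disc.extend(idx_by[s][:k])
        val.extend(idx_by[s][k:])
    disc = np.sort(np.array(disc, dtype=int))
    val = np.sort(np.array(val, dtype=int))
    assert len(disc) == n_disc and len(disc) + len(val) == n
    return disc, val


def derive_labels(
    clinical: pd.DataFrame,
    task: TaskDefinition | str,
    tmb_cutpoint: float = synthetic.TMB_CUTPOINT,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary labels and inclusion mask for one task.

    Returns ``(labels, included)`` aligned with the table rows; labels are
    only meaningful where ``included`` is True.  Unknown subtype codes raise.
    """
    if isinstance(task, str):
        task = TASKS[task]
    subtype = clinical["subtype"].to_numpy()
    unknown = set(subtype) - set(synthetic.SUBTYPES)
    if unknown:
        raise ValidationError(f"unknown subtype code(s): {sorted(unknown)}")
    if task.name == "mmr":
        included = ~np.isin(subtype, task.excluded_subtypes)
        labels = (subtype == "MMR-D").astype(int)
    elif task.name == "tmb":
        included = np.ones(len(clinical), dtype=bool)
        labels = (clinical["tmb"].to_numpy(dtype=float) > tmb_cutpoint).astype(int)
    else:  # pragma: no cover - guarded by TASKS
        raise ValidationError(f"unsupported task {task.name!r}")
    if not included.any():
        raise ValidationError("no lesions left after task exclusions")
    return labels, included


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical covariates used by the classifier:
    age numeric, histology one-hot, grade and stage binary."""
    out = pd.DataFrame(index=clinical.index)
    out["clin_age"] = clinical["age"].astype(float)
    for h in synthetic._HISTOLOGIES:
        out[f"clin_histology_{h}"] = (clinical["histology"] == h).astype(float)
    out["clin_grade_poor"] = (clinical["grade"] == "poor").astype(float)
    out["clin_stage_extrauterine"] = (
        clinical["stage"] == "extra_uterine").astype(float)
    return out


# ---------------------------------------------------------------------------
# Cohort-level feature extraction
# ---------------------------------------------------------------------------

def extract_cohort_features(
    cohort: synthetic.PhantomCohort,
    margin_mm: float = 3.0,
    n_bins: int = 32,
    target_spacing: float = 1.0,
) -> pd.DataFrame:
    """Resample, build rims, and extract the 200-feature vector per lesion.

    Volumes already on the target isotropic grid skip the resampling step.
    Returns a rectangular table: 200 radiomic columns, clinical covariates,
    and the subtype/TMB labels, indexed by patient id.
    """
    rows = []
    for vol, mask, rec in zip(cohort.volumes, cohort.masks, cohort.clinical):
        if tuple(vol.spacing) != (target_spacing,) * 3:
            vol, mask = imaging.resample_isotropic(vol, mask, target_spacing)
        regions = imaging.make_regions(mask, margin_mm)
        vec = feat.extract_lesion_features(vol, regions, n_bins)
        vec.update({k: getattr(rec, k) for k in CLINICAL_COLUMNS})
        vec.update({k: getattr(rec, k) for k in LABEL_COLUMNS})
        vec["patient_id"] = rec.patient_id
        rows.append(vec)
    df = pd.DataFrame(rows).set_index("patient_id")
    radiomic = [c for c in df.columns
                if c.startswith(("intratumoral_", "rim_"))]
    assert len(radiomic) == 2 * len(feat.FEATURE_MANIFEST)
    return df


def radiomic_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(("intratumoral_", "rim_"))]


def load_cohort(data_dir) -> synthetic.PhantomCohort:
    """Read a cohort written by :func:`rimradiomics.synthetic.write_cohort`
    (NIfTI volumes/masks + clinical.csv)."""
    data_dir = Path(data_dir)
    clinical = pd.read_csv(data_dir / "clinical.csv")
    volumes, masks, records = [], [], []
    for _, row in clinical.iterrows():
        pid = row["patient_id"]
        volumes.append(imaging.read_volume(data_dir / f"{pid}_ct.nii.gz"))
        masks.append(imaging.read_mask(data_dir / f"{pid}_tumor.nii.gz"))
        records.append(synthetic.ClinicalRecord(**row.to_dict()))
    registry_path = data_dir / "planted_registry.json"
    registry = (json.loads(registry_path.read_text())
                if registry_path.exists() else {})
    return synthetic.PhantomCohort(volumes, masks, records, registry)


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

class _JsonLog:
    def __init__(self, path=None):
        self.path = Path(path) if path else None
        if self.path:
            self.path.write_text("")

    def emit(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        logger.info("%s: %s", stage, fields)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(
    config: PipelineConfig,
    cohort: synthetic.PhantomCohort | None = None,
    feature_table: pd.DataFrame | None = None,
) -> evaluate.EvaluationReport:
    """Execute one classification task end-to-end.

    Inputs come from, in order of precedence: a precomputed `feature_table`
    (columns as produced by :func:`extract_cohort_features`), an in-memory
    `cohort`, ``config.data_dir`` (NIfTI + CSV on disk), or
    ``config.simulation`` (phantoms generated on the fly).  Artifacts are
    written to ``config.out_dir`` when set.

    The returned report carries the attributes ``selection_report``,
    ``fitted_model`` and ``frequency_table`` for downstream inspection.
    """
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2 ** 31 - 1))
             for k in ("simulate", "split", "cascade", "rfe")}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log = _JsonLog(out_dir / "log.jsonl" if out_dir else None)

    if feature_table is None:
        if cohort is None:
            if config.data_dir:
                cohort = load_cohort(config.data_dir)
            else:
                sim = config.simulation or synthetic.SimulationConfig()
                sim = dataclasses.replace(sim, seed=seeds["simulate"])
                cohort = synthetic.generate_cohort(sim)
        log.emit("cohort", n=len(cohort))
        feature_table = extract_cohort_features(
            cohort, config.margin_mm, config.n_bins)
    table = feature_table
    log.emit("extract", n_lesions=len(table),
             n_radiomic=len(radiomic_columns(table)))

    task = TASKS[config.task]
    labels_all, included = derive_labels(table, task, config.tmb_cutpoint)
    table = table.loc[included]
    y = labels_all[included]
    log.emit("labels", task=task.name, n_included=len(table),
             n_positive=int(y.sum()))

    strata = table["subtype"].astype(str) + "|" + pd.Series(
        y, index=table.index).astype(str)
    disc_idx, val_idx = split_cohort(
        len(table), config.split_fraction, strata.to_numpy(), seeds["split"])
    disc, val = table.iloc[disc_idx], table.iloc[val_idx]
    y_disc, y_val = y[disc_idx], y[val_idx]
    log.emit("split", n_discovery=len(disc), n_validation=len(val),
             pos_discovery=int(y_disc.sum()), pos_validation=int(y_val.sum()))

    rad_cols = radiomic_columns(table)
    report = selection.run_cascade(
        disc[rad_cols], y_disc, disc["scanner"].to_numpy(),
        alpha=config.selection_alpha, mrmr_fraction=config.mrmr_fraction,
        prefilter_kwargs=config.prefilter, seed=seeds["cascade"])
    survivors = report.selected
    log.emit("selection", **{s.name: s.n_out for s in report.stages})

    disc_X = pd.concat([disc[survivors], encode_clinical(disc)], axis=1)
    val_X = pd.concat([val[survivors], encode_clinical(val)], axis=1)
    disc_z, val_z, z_params = selection.zscore_standardize(disc_X, val_X)

    rfe_cfg = dataclasses.replace(config.rfe, seed=seeds["rfe"])
    model = classify.rfe_rf_train(disc_z, y_disc, rfe_cfg)
    relevant = sorted(classify.relevant_features(model.frequencies))
    log.emit("train", best_size=model.best_size, cv_auroc=model.cv_auroc,
             total_analysis_folds=model.frequencies.total,
             n_relevant=len(relevant))

    scores_val = classify.predict_scores(model, val_z)
    (cv_auc, _), (test_auc, test_ci), delong_p = evaluate.delong_ci_and_test(
        model.cv_scores, model.cv_labels, scores_val, y_val)
    metrics = evaluate.confusion_metrics((scores_val >= 0.5).astype(int), y_val)
    assoc_cols = [c for c in relevant if c in table.columns]
    assoc = (evaluate.mannwhitney_bh(table[assoc_cols], y)
             if assoc_cols else None)

    result = evaluate.EvaluationReport(
        task=task.name, n_discovery=len(disc), n_validation=len(val),
        cv_auroc=float(cv_auc), test_auroc=float(test_auc),
        test_auroc_ci=test_ci, delong_p=float(delong_p),
        metrics=metrics, feature_associations=assoc,
        selected_features=model.selected_features,
        relevant_features=relevant)
    # side artifacts for callers and the CLI
    result.selection_report = report
    result.fitted_model = model
    result.frequency_table = model.frequencies
    result.validation_scores = scores_val
    result.validation_labels = y_val
    result.discovery_ids = list(disc.index)
    result.validation_ids = list(val.index)
    log.emit("evaluate", test_auroc=float(test_auc), delong_p=float(delong_p))

    if out_dir:
        feature_table.to_csv(out_dir / "features.csv")
        with open(out_dir / "selection.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        with open(out_dir / "model.json", "w") as fh:
            json.dump({
                "task": task.name,
                "selected_features": model.selected_features,
                "best_size": model.best_size,
                "cv_auroc": model.cv_auroc,
                "selection_frequencies": model.frequencies.counts,
                "total_analysis_folds": model.frequencies.total,
                "zscore_params": z_params,
            }, fh, indent=2, sort_keys=True)
        joblib.dump(model.forest, out_dir / "forest.joblib")
        with open(out_dir / "evaluation.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        (out_dir / "evaluation.txt").write_text(
            evaluate.format_report(result))
        evaluate.roc_coordinates(scores_val, y_val).to_csv(
            out_dir / "roc_validation.csv", index=False)
        with open(out_dir / "feature_manifest.json", "w") as fh:
            json.dump(feat.feature_manifest(), fh, indent=2)
    return result
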