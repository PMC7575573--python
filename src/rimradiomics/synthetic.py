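"""Synthetic CT tumor phantoms and clinical covariates.

The generator emulates the statistical structure of a 150-patient
endometrial-cancer CE-CT cohort so that every downstream stage (rim
construction, feature extraction, selection cascade, nested RFE-RF
classification, evaluation) is testable without patient data:

* four molecular subtypes (POLE / MMR-D / CN-low-like / CN-high-like) at the
  cohort proportions 4% / 29.3% / 18.7% / 48%;
* tumor mutational burden (TMB, mut/Mb) drawn log-normally per subtype, with
  MMR-D parameterized so ~90% of its mass lies above the 15.5 mut/Mb TMB-high
  cut-point and POLE essentially always above it, while the copy-number
  subtypes are almost always below it;
* the class-discriminating imaging signal is *extra high-frequency texture in
  a ±2 mm shell around the tumor boundary* (hypermutated subtypes get a
  larger noise amplitude there), mirroring an analysis in which
  peritumoral-rim features carry the signal; the effect multiplier is
  configurable, including zero for null cohorts;
* scanner-manufacturer batch effects: an additive HU offset plus a mild
  noise-sd multiplier per manufacturer, which makes intensity-location (and,
  weakly, variance-type) features "unstable" across scanners — exactly what
  the Kruskal–Wallis stability filter is meant to remove;
* clinical covariates (age, histology, grade, FIGO stage) drawn from
  class-conditional distributions whose class association strength is
  configurable.

Tumors are noisy ellipsoids, not anatomically realistic uteri: the pipeline
consumes only intensities inside and near the VOI, so lesion-scale texture —
not organ anatomy — is what must be emulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imaging import CTVolume, VOIMask, ValidationError, write_mask, write_volume

__all__ = [
    "LesionSpec",
    "SimulationConfig",
    "ClinicalRecord",
    "PhantomCohort",
    "generate_phantom",
    "generate_cohort",
    "write_cohort",
    "SUBTYPES",
    "TMB_CUTPOINT",
]

SUBTYPES = ("POLE", "MMR-D", "CN-low-like", "CN-high-like")
TMB_CUTPOINT = 15.5  # mut/Mb; TMB-high is strictly greater

# Class-conditional clinical distributions (hypermutated subtypes skew
# endometrioid / lower-grade; CN-high-like skews serous / advanced stage).
_HISTOLOGIES = ("endometrioid", "serous", "clear_cell", "carcinosarcoma",
                "undifferentiated", "unclassified_high_grade")
_HISTOLOGY_P = {
    "POLE":         (0.80, 0.05, 0.05, 0.02, 0.04, 0.04),
    "MMR-D":        (0.62, 0.05, 0.05, 0.08, 0.10, 0.10),
    "CN-low-like":  (0.75, 0.02, 0.08, 0.05, 0.02, 0.08),
    "CN-high-like": (0.10, 0.40, 0.08, 0.30, 0.02, 0.10),
}
_POOR_GRADE_P = {"POLE": 0.20, "MMR-D": 0.25, "CN-low-like": 0.10,
                 "CN-high-like": 0.40}
_EXTRAUTERINE_P = {"POLE": 0.35, "MMR-D": 0.50, "CN-low-like": 0.40,
                   "CN-high-like": 0.70}
_AGE_MEAN = {"POLE": 58.0, "MMR-D": 64.0, "CN-low-like": 61.0,
             "CN-high-like": 66.0}

# log-TMB (natural log of mut/Mb) location/scale per subtype; MMR-D places
# ~91% of its mass above the 15.5 mut/Mb cut-point, POLE ~100%, CN ~2%.
_DEFAULT_TMB = {
    "POLE": (4.6, 0.40),
    "MMR-D": (3.55, 0.60),
    "CN-low-like": (1.6, 0.55),
    "CN-high-like": (1.6, 0.55),
}


@dataclass
class LesionSpec:
    """Per-lesion phantom parameters."""

    radii_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    tumor_hu: float = 80.0
    background_hu: float = 30.0
    noise_sd: float = 12.0
    rim_heterogeneity_effect: float = 0.0   # extra shell noise, in noise_sd units
    shell_halfwidth_mm: float = 2.0
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_margin_mm: float = 5.0             # background beyond the dilated VOI


@dataclass
class ClinicalRecord:
    """Clinical covariates and labels for one patient/lesion."""

    patient_id: str
    age: float
    histology: str
    grade: str            # "well_moderate" | "poor"
    stage: str            # "uterine_confined" | "extra_uterine"
    scanner: str
    subtype: str
    tmb: float            # mut/Mb


@dataclass
class SimulationConfig:
    """Cohort-level generator settings; defaults are the study conditions."""

    n_patients: int = 150
    class_proportions: dict[str, float] = field(default_factory=lambda: {
        "POLE": 0.04, "MMR-D": 0.293, "CN-low-like": 0.187,
        "CN-high-like": 0.48,
    })
    rim_heterogeneity_effect: dict[str, float] = field(default_factory=lambda: {
        "POLE": 3.0, "MMR-D": 3.0, "CN-low-like": 0.0, "CN-high-like": 0.0,
    })
    scanner_labels: dict[str, float] = field(default_factory=lambda: {
        "GE": 0.5, "Siemens": 0.3, "Philips": 0.2,
    })
    scanner_shift: dict[str, float] = field(default_factory=lambda: {
        "GE": 0.0, "Siemens": 12.0, "Philips": -8.0,
    })
    scanner_noise_scale: dict[str, float] = field(default_factory=lambda: {
        "GE": 1.0, "Siemens": 1.1, "Philips": 0.95,
    })
    tmb_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TMB))
    tumor_radius_range: tuple[float, float] = (6.0, 12.0)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 12.0
    clinical_effect: float = 1.0    # 0 = class-independent covariates
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"class proportions must sum to 1, got {total}")
        if any(r <= 0 for r in self.tumor_radius_range):
            raise ValidationError("tumor radii must be positive")
        if self.noise_sd < 0 or any(v < 0 for v in
                                    self.rim_heterogeneity_effect.values()):
            raise ValidationError("noise amplitudes must be >= 0")
        sc = sum(self.scanner_labels.values())
        if abs(sc - 1.0) > 1e-9:
            raise ValidationError("scanner probabilities must sum to 1")


@dataclass
class PhantomCohort:
    """Generated volumes, masks, clinical table and planted-effect registry."""

    volumes: list[CTVolume]
    masks: list[VOIMask]
    clinical: list[ClinicalRecord]
    planted_feature_registry: dict

    def __len__(self) -> int:
        return len(self.volumes)


def generate_phantom(spec: LesionSpec, seed: int) -> tuple[CTVolume, VOIMask]:
    """One ellipsoidal tumor phantom on a noisy background.

    The tumor is an ellipsoid of ``tumor_hu`` on a ``background_hu`` field
    with Gaussian voxel noise; if ``rim_heterogeneity_effect > 0``, extra
    white (high-frequency) noise of amplitude ``effect * noise_sd`` is added
    in a shell of ±``shell_halfwidth_mm`` around the tumor boundary.  The
    grid leaves ``grid_margin_mm`` of background beyond the tumor so a 3 mm
    dilation fits (values below 4 mm are rejected).
    """
    radii = np.asarray(spec.radii_mm, dtype=float)
    if np.any(radii <= 0):
        raise ValidationError(f"radii must be positive, got {radii}")
    if spec.grid_margin_mm < 4.0:
        raise ValidationError(
            "grid margin must be >= 4 mm to leave room for a 3 mm dilation")
    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    half_mm = radii + spec.grid_margin_mm
    half_vox = np.ceil(half_mm / spacing).astype(int)
    shape = tuple(2 * half_vox + 1)

    rng = np.random.default_rng(seed)
    # physical coordinates of voxel centers relative to the tumor center
    axes = [(np.arange(n) - h) * s for n, h, s in zip(shape, half_vox, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    # signed "radial excess" in mm: <=0 inside the ellipsoid.  For spheres it
    # is exact; for ellipsoids it is the scaled-radius approximation.
    r_norm = np.sqrt((xx / radii[0]) ** 2 + (yy / radii[1]) ** 2
                     + (zz / radii[2]) ** 2)
    mean_r = float(np.mean(radii))
    dist_to_boundary = (r_norm - 1.0) * mean_r
    mask = (r_norm <= 1.0).astype(np.uint8)

    vol = np.full(shape, spec.background_hu, dtype=np.float64)
    vol[mask > 0] = spec.tumor_hu
    vol += rng.normal(0.0, spec.noise_sd, size=shape)
    if spec.rim_heterogeneity_effect > 0:
        shell = np.abs(dist_to_boundary) <= spec.shell_halfwidth_mm
        vol[shell] += rng.normal(
            0.0, spec.rim_heterogeneity_effect * spec.noise_sd,
            size=int(shell.sum()))
    sp = tuple(float(s) for s in spacing)
    return CTVolume(vol, sp), VOIMask(mask, sp)


def _choice(rng: np.random.Generator, items, probs) -> str:
    return str(items[rng.choice(len(items), p=np.asarray(probs, float))])


def _blend(p_class, p_marginal, strength):
    p = strength * np.asarray(p_class, float) + (1 - strength) * np.asarray(
        p_marginal, float)
    return p / p.sum()


def generate_cohort(config: SimulationConfig) -> PhantomCohort:
    """Draw a full phantom cohort from `config` (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[k] for k in labels])
    scanners = list(config.scanner_labels)
    scanner_p = np.array([config.scanner_labels[k] for k in scanners])
    hist_marginal = np.mean([_HISTOLOGY_P[s] for s in SUBTYPES], axis=0)
    w = float(np.clip(config.clinical_effect, 0.0, 1.0))

    volumes, masks, clinical = [], [], []
    for i in range(config.n_patients):
        subtype = _choice(rng, labels, probs)
        scanner = _choice(rng, scanners, scanner_p)
        lo, hi = config.tumor_radius_range
        radii = tuple(rng.uniform(lo, hi, size=3))
        effect = float(config.rim_heterogeneity_effect.get(subtype, 0.0))
        noise_sd = config.noise_sd * float(
            config.scanner_noise_scale.get(scanner, 1.0))
        spec = LesionSpec(
            radii_mm=radii,
            noise_sd=noise_sd,
            rim_heterogeneity_effect=effect,
            voxel_spacing=config.voxel_spacing,
        )
        lesion_seed = int(rng.integers(0, 2 ** 31 - 1))
        vol, mask = generate_phantom(spec, lesion_seed)
        vol.intensities += float(config.scanner_shift.get(scanner, 0.0))

        mu, sigma = config.tmb_distributions[subtype]
        tmb = float(np.exp(rng.normal(mu, sigma)))
        age = float(np.clip(rng.normal(
            w * _AGE_MEAN[subtype] + (1 - w) * 64.0, 9.0), 35.0, 92.0))
        histology = _choice(
            rng, _HISTOLOGIES, _blend(_HISTOLOGY_P[subtype], hist_marginal, w))
        p_poor = w * _POOR_GRADE_P[subtype] + (1 - w) * 0.27
        grade = "poor" if rng.random() < p_poor else "well_moderate"
        p_extra = w * _EXTRAUTERINE_P[subtype] + (1 - w) * 0.56
        stage = "extra_uterine" if rng.random() < p_extra else "uterine_confined"

        volumes.append(vol)
        masks.append(mask)
        clinical.append(ClinicalRecord(
            patient_id=f"P{i:03d}", age=age, histology=histology, grade=grade,
            stage=stage, scanner=scanner, subtype=subtype, tmb=tmb))

    registry = {
        "rim_heterogeneity_effect": dict(config.rim_heterogeneity_effect),
        # rim-difference features respond to the boundary-shell noise; any
        # rim_* texture feature recovered downstream counts as planted signal
        "planted_rim_prefix": "rim_",
        "scanner_shift": dict(config.scanner_shift),
        "scanner_noise_scale": dict(config.scanner_noise_scale),
        # additive HU shifts move intensity-location features; these are the
        # features the stability filter is expected to flag
        "scanner_affected_features": [
            "firstorder_mean", "firstorder_minimum", "firstorder_maximum",
            "firstorder_p10", "firstorder_p25", "firstorder_median",
            "firstorder_p75", "firstorder_p90", "firstorder_energy",
            "firstorder_rms",
        ],
        "tmb_cutpoint": TMB_CUTPOINT,
        "seed": config.seed,
    }
    return PhantomCohort(volumes, masks, clinical, registry)


def write_cohort(cohort: PhantomCohort, out_dir) -> None:
    """Write NIfTI volumes/masks, the clinical CSV and the planted-effect
    registry JSON to `out_dir`."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for vol, mask, rec in zip(cohort.volumes, cohort.masks, cohort.clinical):
        write_volume(vol, out / f"{rec.patient_id}_ct.nii.gz")
        write_mask(mask, out / f"{rec.patient_id}_tumor.nii.gz")
    pd.DataFrame([dataclasses.asdict(r) for r in cohort.clinical]).to_csv(
        out / "clinical.csv", index=False)
    with open(out / "planted_registry.json", "w") as fh:
        json.dump(cohort.planted_feature_registry, fh, indent=2)
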