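# Methods

`rimradiomics` implements a clinical-radiomic classification pipeline for
contrast-enhanced CT of endometrial tumors: it predicts molecular phenotype —
mismatch-repair deficiency (MMR-D) versus the copy-number-based subtypes, and
tumor-mutational-burden-high (TMB > 15.5 mut/Mb) versus TMB-low — from
texture features computed inside the tumor volume-of-interest (VOI) and in a
3 mm peritumoral rim. Because patient images are not distributable, the
package ships a phantom generator that reproduces the statistical structure
the analysis assumes, so every stage is exercised end-to-end on synthetic
data.

## Pipeline

1. **Resampling.** Volumes are resampled to an isotropic 1 mm³ grid
   (trilinear for intensities, nearest-neighbor for masks, 0.5 threshold so
   masks stay binary). The output grid covers the input's physical extent;
   coordinates follow the voxel-center convention with world positions taken
   from the NIfTI affine.
2. **Rim construction.** The tumor VOI is dilated by 3 mm using a Euclidean
   distance transform in *physical millimetres* (not structuring-element
   steps), so the margin is honoured on anisotropic grids too; the rim is
   the dilated mask minus the tumor mask. Dilation happens after resampling,
   making the 3 mm shell grid-independent. On the 1 mm grid a single voxel
   dilates to the 123-point lattice ball of radius 3.
3. **Feature extraction.** A fixed 100-feature panel (versioned manifest) is
   evaluated on the tumor mask and on the dilated mask; the peritumoral-rim
   features are the differences `rim_f = f(dilated) − f(tumor)`, giving
   exactly 200 named values per lesion. Rim features therefore satisfy
   `rim_f + f(tumor) = f(dilated)` identically.
4. **Selection cascade** (discovery cohort only): Kruskal–Wallis
   scanner-stability filter → mRMR → elastic-net prefilter, then z-score
   standardization with training parameters applied unchanged to the
   held-out cohort. Clinical covariates (age, histology one-hot, binary
   grade and FIGO-stage groupings) bypass the cascade and are appended
   before classification.
5. **Classification.** A recursive-feature-elimination random forest with
   repeated nested cross-validation; see below.
6. **Evaluation.** AUROC (Mann–Whitney form), DeLong variance/CIs and the
   unpaired DeLong comparison of training-CV versus held-out AUROC,
   sensitivity/specificity/PPV/NPV with exact Clopper–Pearson 95% CIs at the
   0.5 operating point (configurable; the operating point is a documented
   choice), and per-feature Mann–Whitney tests with Benjamini–Hochberg
   adjustment for the relevant-feature set.

## The feature panel

There is no single canonical 100-feature list for this kind of analysis, so
the repository fixes its own versioned manifest — exactly 100 features per
region, drawn from the families above:

| family | count | notes |
| --- | --- | --- |
| first-order | 19 | population moments; entropy/uniformity on discretized levels; non-excess kurtosis; skewness/kurtosis = 0 on constant regions |
| GLCM | 24 | distance 1, 13 unique 3D directions, symmetric, per-direction features averaged |
| GLRLM | 16 | 13 directions, averaged |
| GLSZM | 16 | zones by 26-connectivity |
| NGTDM | 5 | 26-neighborhood, out-of-mask neighbors excluded |
| NGLDM | 12 | dependence = 1 + equal-level 26-neighbors (tolerance 0) |
| Gabor | 8 | 4 orientations (0°, 45°, 90°, 135°) × 2 wavelengths (4, 8 mm), 2D per axial slice, in-mask mean magnitude |

Numerical conventions: gray levels are 1..32 by within-region min–max
equal-width binning (constant regions map to level 1); logarithms are base
2; texture requires ≥ 27 voxels (neighborhoods and runs are ill-defined
below a 3×3×3 core); GLCM correlation on zero-variance regions is 0; NGTDM
coarseness with a zero denominator is 10⁶; Gabor kernels are made exactly
DC-free and slices are edge-replicated before convolution so flat regions
and image borders contribute no response. The GLCM set retains two
classical linearly dependent pairs (sum average = 2 × joint average, sum
variance = cluster tendency), as the field's standard toolkits historically
did; the redundancy-aware selection stages make this harmless. The Gabor
orientation label is the grating wave-vector angle measured from the first
in-plane axis.

Min–max discretization makes all matrix-family features invariant to
affine intensity shifts; this is what lets an additive scanner offset
perturb only first-order location features.

## Selection cascade

* **Stability filter.** Kruskal–Wallis across scanner-manufacturer groups,
  α = 0.05 uncorrected (an aggressive filter is the conservative
  harmonization choice); needs ≥ 2 groups of ≥ 3 lesions, otherwise skipped
  with a warning; constant features are retained (no variation to test).
  Under permuted scanner labels the removal rate is calibrated at ≈ α.
* **mRMR.** Greedy difference form (MID): score = MI(f; y) − mean MI(f; s)
  over the already-selected set, with MI on 3-bin equal-frequency
  discretizations; ties break lexicographically by feature id, making the
  ranking deterministic. Exactly ⌈0.8 n⌉ features are retained (ceiling —
  the inclusive reading of "top 80%").
* **Elastic-net prefilter.** Logistic elastic net (saga), hyperparameters
  (l1_ratio ∈ {0.5, 0.9} × C ∈ {0.1, 1.0}) tuned by repeated stratified
  5-fold CV × 10 repetitions maximizing mean validation AUROC, with the
  minority class upsampled with replacement *inside training folds only*;
  ties prefer the stronger penalty. Importance is the mean absolute
  coefficient (on z-scored features) over per-repeat refits at the chosen
  hyperparameters; "importance > 0" means a nonzero mean absolute
  coefficient. The survivor count is data-dependent and not enforced.
* **z-scoring** uses the sample standard deviation (ddof = 1); zero-variance
  columns pass through as 0 with a warning.

All cascade statistics and the z-score parameters are computed on the
discovery split only; a test perturbs held-out rows and asserts the selected
set is unchanged (leakage audit).

## Nested RFE-RF

The design follows a caret-style nested scheme: `repeats × 5` outer folds;
within each outer training fold, 5 inner folds. Per inner fold a
2000-tree random forest (inverse-frequency class weights; no resampling at
this stage) ranks features by Gini impurity importance, candidate subset
sizes ({2, 4, 8, 16, 32, all} by default) are evaluated on the inner
validation fold, and the best subset of that *analysis fold* increments a
per-feature selection-frequency table. With the default 10 repeats the
table spans exactly 250 analysis folds. A feature is **relevant** when
selected in strictly more than 10% of analysis folds (> 25/250); the
historical "Gini importance > 25.0" reading coincides with this raw fold
count. Per outer fold the subset size maximizing mean inner AUROC is kept
(ties toward the smaller size); the final forest is refit on the full
discovery set at the modal best size. Cross-validated AUROC uses per-sample
outer-fold held-out scores averaged over repeats. Stratified folds whose
training or validation side would be single-class are re-drawn; an
unresolvable stratification (minority smaller than the fold count) raises.
All randomness derives from a single pipeline seed via deterministic
sub-seeds, so identical (config, seed) pairs reproduce byte-identical
reports.

## Statistics

AUROC is the normalized Mann–Whitney statistic (ties 0.5). DeLong variance
comes from the sample covariance of placement values; the train-vs-test
comparison uses the *unpaired* two-sample form (the cohorts are disjoint)
with a normal reference for the z statistic — R's pROC computes the same
statistic and variances (verified in a test) but refers it to a
Satterthwaite t. Degenerate variances (AUROC exactly 0 or 1) clamp the CI
and set the comparison p to NaN, except that a zero difference is p = 1
exactly. Mann–Whitney feature tests use exact enumeration below 8 per group
(no ties) and the tie-corrected normal approximation otherwise; constant
features get p = 1 by convention.

## The phantom generator

Each lesion is a noisy ellipsoid (tumor ≈ 80 HU on a 30 HU background,
voxel noise σ = 12 HU, radii uniform in 6–12 mm) on a grid that leaves ≥ 5
mm of background beyond the tumor. Tumors are deliberately not
anatomically realistic: the pipeline consumes only intensities inside and
near the VOI, so lesion-scale texture is the thing to emulate. The
class-discriminating signal is extra white noise of amplitude
`effect × σ` in a ±2 mm shell around the tumor boundary — boundary-localized
heterogeneity, mirroring an analysis in which peritumoral-rim features carry
the signal — with default multipliers 3.0 for the hypermutated subtypes
(MMR-D, POLE) and 0 for the copy-number subtypes; setting every multiplier
to 0 yields a null cohort. Subtype proportions default to 4% POLE, 29.3%
MMR-D, 18.7% CN-low-like, 48% CN-high-like — the published endometrial
molecular-subtype distribution the cohort emulates at n = 150. TMB is log-normal per subtype, parameterized so ~91% of
MMR-D mass and essentially all POLE mass lies above the 15.5 mut/Mb
cut-point while the CN subtypes sit almost entirely below it. Scanner batch
effects are an additive HU offset (0 / +12 / −8 for the three simulated
manufacturers) plus a mild noise-σ multiplier (1.0 / 1.1 / 0.95): the offset
makes intensity-location features scanner-unstable (the stability filter's
intended prey) without touching discretized texture. Clinical covariates are
drawn from subtype-conditional distributions whose association strength is a
single `clinical_effect` dial (0 = independent).

What the phantoms do **not** emulate: organ anatomy and partial-volume
boundaries, contrast-phase and acquisition-protocol variation, segmentation
variability, spatially correlated CT noise, and multi-lesion disease.
Passing tests therefore demonstrate that the *pipeline machinery* recovers a
boundary-localized texture signal under realistic cohort structure — not
that real endometrial tumors are classifiable at any particular accuracy.

## Problem sizes used by the test and acceptance runs

The code defaults are the full printed configuration (2000 trees, 10
repeats, subset grid {2, 4, 8, 16, 32, all}). The automated checks scale
the *problem sizes* down, never the contracts: end-to-end synthetic runs
use 200-tree forests, one CV repeat and a single candidate subset size (8);
the 250-analysis-fold bookkeeping check runs the full 10×5×5 design with
200 trees on a reduced feature table. The null-calibration bound
(validation AUROC within [0.30, 0.70]) reflects AUROC sampling variance at
a 45-lesion validation set.

## Known limitations

* The 100-feature manifest is this package's own fixed panel; other
  radiomics toolkits with the same family structure may differ in exact
  membership.
* Aggregation choices (per-direction feature averaging rather than merged
  matrices; 2D Gabor per axial slice) are one documented selection among
  standard variants.
* The order of resampling and dilation is a genuine design choice; this
  package resamples first so the 3 mm shell is grid-independent.
* The harmonization step is the stability filter only; no ComBat-style
  batch correction.
* Confusion-matrix metrics use the 0.5 vote-fraction operating point; an
  analysis tuned via Youden's index would report different sensitivities at
  the same AUROC.
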