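# Methods

This note documents the modelling conventions behind `noduleomics`: what
each stage computes, the defaults and why, what the synthetic phantoms do
and do not emulate, and the numerical contracts for degenerate inputs.

## ROI model

A case is a 3-D intensity volume in Hounsfield units with per-axis voxel
spacing in mm, plus a binary intranodular mask. The perinodular ring is
defined geometrically:

> ring(d) = { voxels v ∉ intra : min over intra voxels u of
> ‖(v − u) ∘ spacing‖₂ ≤ d }, clipped to the grid,

with d = 15 mm by default. Distance is physical (a Euclidean distance
transform with the anisotropic spacing as sampling), **not** a per-axis
voxel dilation: with 2.5–3 mm slices a voxel dilation would reach ~3×
further through-plane than in-plane. The ring is not masked to lung
parenchyma — it is a pure dilation of the nodule contour, so on real
data chest wall or vessels inside the shell are included (logged as a
caveat). Masks with more than one 26-connected component are reduced to
the largest (an SPN is by definition solitary); ties break on the
smallest linear voxel index, so the choice is deterministic.

## Feature extraction

Exactly 107 features per ROI: 14 shape, 18 first-order, 24 GLCM,
16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM. Conventions (each a config knob or
documented constant):

* **Discretization** — fixed bin width, default 25 HU, per ROI over its
  own intensity range: `level = floor(x/w) − floor(min/w) + 1`. Intra
  and peri ROIs are discretized independently.
* **No resampling** — features are computed on the native grid; shape
  math is spacing-aware.
* **GLCM** — symmetric, Chebyshev distance 1, the 13 unique 3-D
  directions; features computed per direction and averaged. GLRLM runs
  use the same 13 directions, also averaged. GLSZM zones are
  26-connected components of constant level. GLDM uses similarity
  threshold α = 0 on the 26-neighbourhood, and the dependence index of a
  voxel is 1 + the number of equal-level in-ROI neighbours (the voxel
  counts as dependent on itself, so the index runs 1..27). NGTDM counts
  only voxels with at least one in-ROI neighbour.
* **Mesh** — surface area and mesh volume come from marching cubes run
  directly on the (zero-padded) binary mask at level 0.5, with the
  anisotropic spacing applied; volume by the divergence theorem over the
  triangulation. Sphericity is (36π V²)^{1/3} / A. For a single voxel
  the mesh is the regular octahedron with circumradius ½ voxel
  (V = 1/6, A = √3 for unit spacing), giving sphericity π^{1/3}/√3 ≈
  0.8456 — the closed form used as a test oracle. Triangulating a
  binary mask overestimates the area of smooth surfaces by ~8 %
  (staircase bias), so a digitized ball of radius 20 voxels scores
  ≈ 0.92 rather than ≈ 1; absolute sphericity values are therefore
  mesher-specific, while orderings (spiculated < smooth, monotone in
  radius) are preserved. Smoothing the mask before meshing was rejected
  because small ROIs then never cross the iso-level.
* **Axis-labelled diameters** — Maximum2DDiameterSlice/Column/Row are
  the largest in-plane pairwise distances over planes of constant z, x
  and y respectively, computed from voxel centres via per-plane convex
  hulls. Principal axis lengths are 4√λ of the (n−1)-normalised
  covariance eigenvalues of the physical voxel coordinates.
* **Degenerate contracts** — no feature is ever NaN. A constant ROI has
  Variance = Entropy = 0, Uniformity = 1, and GLCM Correlation = 1 (a
  constant level is perfectly dependent); a single-voxel ROI has no
  voxel pairs, so GLCM falls back to the single-cell constant matrix,
  NGTDM returns its documented limits (Coarseness 10⁶, others 0), axis
  lengths are 0 and Elongation/Flatness 1. Every degenerate fallback is
  logged.

Every texture matrix is verified in the test suite against an
independent brute-force voxel/pair/zone/neighbourhood enumeration on
small ROIs, exactly (integer counts).

## Feature selection

Step 1 ranks features by the Fisher Discriminant Ratio
(m₁ − m₂)²/(σ₁² + σ₂²) with sample (n−1) variances, and keeps
⌈0.30 · n_features⌉ (ties broken by name). A zero denominator scores 0
when the means agree and +∞ (ranked first, logged) when they differ.

Step 2 runs 100 repetitions. Each repetition: a stratified 70/30 split
(stratification guarantees both classes in every training part at small
n); standardization statistics from the 70 % part only; an L1-penalised
logistic regression fitted over 50 log-spaced penalties spanning four
decades down from the analytic all-zero penalty
max|Xᵀ(y − ȳ)|/n; the penalty with the best validation accuracy wins,
ties preferring the stronger penalty (sparser model). The 10 features
with the largest |coefficient| (ties: larger |coefficient|, then name)
are credited; if fewer than 10 coefficients are nonzero only those are
credited. Features credited **more than 60** times (≥ 61) survive.
"LASSO on a binary outcome" is interpreted as the logistic link; a
coordinate-descent linear-regression variant on ±1 labels is available
via `link="linear"`. The FDR pool is computed once globally;
`rerank_per_split=True` re-ranks within each repetition's training part
instead. Selection is scale-invariant (standardization) and never sees
the held-out split — the API accepts only the training table.

## Classification

RBF-SVM over C ∈ {10⁻²…10³}, γ ∈ {10⁻⁴…10¹} (log steps). For every
pair, validation accuracy is averaged over 100 stratified 70/30
partitions shared across the grid (a paired comparison); the best pair
is refitted on the full training table and probabilities come from a
Platt sigmoid (Newton fit with smoothed targets) on the training
decision values. No class weighting by default — an imbalanced training
cohort is allowed to produce the high-specificity/low-sensitivity
behaviour such protocols show — with `class_weight="balanced"` as an
option. Evaluation fixes the probability threshold at 0.5 with LC as
the positive class; the ROC is built over all unique probability
cutoffs (tied scores collapse to one operating point, making the
trapezoidal AUC equal to the normalized Mann–Whitney U with ties
counted ½ — asserted against a pairwise oracle). Models serialize to
JSON as plain arrays (support vectors, dual coefficients,
standardization, calibration), so a round-trip reproduces probabilities
bit-for-bit.

## Cohort statistics

Pearson chi-square without continuity correction for categorical
features; Welch's t-test from summary statistics by default (the
equal-variance Student form behind a flag) because equal variances
cannot be verified from summaries; Spearman rank correlation with
average-rank ties as the default association measure between radiomics
values and binary semantic flags, with Pearson exposed as an
alternative (both conventions appear in radiology reporting; we compute
whichever is requested and default to Spearman). ICC(2,1) — two-way
random effects, absolute agreement, single rater — is computed from the
two-way ANOVA mean squares and cross-checked against an independent
implementation in the tests. All tests are two-sided at α = 0.05; no
multiple-testing correction is applied.

## Synthetic phantoms

The generator emulates solitary pulmonary nodules ≤ 30 mm on an
anisotropic grid (default spacing 0.7 × 0.7 × 2.5 mm, mirroring
thick-slice chest reconstructions), with a guaranteed ≥ 15 mm clear
margin so the perinodular ring is never truncated (specs violating the
margin are rejected). Defaults: base radius 7 mm with ±15 % per-axis
jitter; LC-like cases add 8 conical spicules (base radius 1.5 mm,
length 5 mm, directions uniform on the sphere) and convert 40 % of
interior voxels — a spatially correlated pocket structure with 3 mm
correlation length — to a ground-glass HU distribution. HU models:
solid 50 ± 15, ground-glass −450 ± 60, lung background −850 ± 40,
additive noise SD 20 HU; plausible chest-CT ranges, configurable, not
estimates of any cohort. The ground-truth mask is computed before noise
(no segmentation-error model, matching a manually segmented workflow).
Generation is bit-deterministic in (seed, class, case index).

What the phantoms do **not** emulate: chest anatomy (vessels, ribs,
pleura), contrast kinetics, scanner/kernel variation, segmentation
error, and realistic inter-feature correlation structure. Passing the
end-to-end checks therefore demonstrates that the pipeline's stages are
implemented correctly and recover planted morphology, not that clinical
discrimination performance would be attained; phantom class contrasts
are intentionally strong, and held-out AUCs near 1 on phantoms carry no
clinical meaning.

## Problem sizes and reproduction

The reproduction script and acceptance tests use desk-scale sizes chosen
once: the end-to-end phantom experiment uses 100 nodules per class with
a stratified 70/30 split; the no-signal null uses 50 per class, with
the selector's 10-seed stability check run on the one extracted null
cohort (the selector's split randomness is the stochastic element under
test); planted-feature recovery uses 150 cases per class with three
2-SD effects among 110 features (33 pooled). Oracle comparisons run on
≤ 6³ ROIs (texture), ≤ 40³ grids (ring) and n = 50 score vectors (AUC).

## Known limitations

* Feature values follow one fixed convention set (bin width, direction
  averaging, mesh); other radiomics software with different defaults
  will produce systematically different absolute values, particularly
  for surface-derived shape features (see the mesh note above).
* The perinodular ring includes non-lung tissue on real data.
* The bootstrap SVM tuning reports the single refit model's held-out
  metrics; the per-pair bootstrap validation scores are exposed on the
  model object but are not an out-of-sample performance estimate.
* DICOM ingestion is out of scope; convert series to NRRD/NIfTI
  upstream.
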