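# Methods

This note documents the statistical models implemented in `langmorph`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model and preparation

Inputs are modulated tissue-density maps (GM or WM) in a common template
space, carried as `VolumeGrid` (3D values + NIfTI affine), plus a subject
table (group, delay status, age, scan center, behavioral scores).

* **Masking** keeps voxels where the study template (voxel-wise mean of
  the cohort's raw maps, clipped to [0, 1]) is *strictly greater* than the
  tissue-probability threshold, default 0.25.
* **Relative volume**: each map is divided by that subject's total tissue
  volume (sum of voxel values × voxel volume, in cm³). The rescaled map
  integrates to exactly 1, which is checked as a conservation invariant.
  This adjusts for head size at the individual level instead of entering
  total volume as a model covariate.
* **Age standardization** (used before PLS): per voxel, OLS residuals of
  value on age with the voxel's cross-subject mean restored. The residual
  scale is deliberately kept (no division by residual SD) — the operation
  removes the age trend without reweighting voxels — and is idempotent.
* Multi-condition analyses (GM + WM) require a **shared voxel register**;
  the convention here is to reuse the first condition's template mask for
  all conditions, so saliences are comparable voxel-by-voxel.

## Voxel-wise GLM and cluster inference

Per masked voxel, ordinary least squares of relative volume on an
intercept, a binary group indicator, centered age, and reference-coded
scan-center dummies. The contrast *t* statistic uses the pooled residual
variance with df = n − rank(X); two one-tailed p maps serve the two
contrast directions.

Cluster-level inference is a **permutation maximum-extent null combined
with Benjamini–Hochberg FDR**, not random-field topological FDR:
suprathreshold voxels (one-tailed p < 0.025 by default) are grouped with
18-neighbor connectivity (faces + edges, the SPM convention); group
labels are permuted *within scan-center strata* (exchangeability respects
the fixed-effect nuisance), the model refit, and the maximum cluster
extent recorded per permutation. A cluster's p is the plain fraction of
permutations whose maximum extent reaches its observed extent; BH across
clusters yields q, flagged at q < 0.05. When fewer distinct within-strata
permutations exist than requested, the exhaustive set is used (with a
warning). This route was chosen because it is assumption-light, exactly
testable on synthetic data, and keeps the same height/q thresholds as the
random-field procedure it replaces; it makes no nonstationarity
correction (see Limitations).

## Conjunction-overlap commonality

For two one-tailed statistic maps A and B on the same mask, at each
threshold of a descending sweep (default P = 0.05 → 0.0001, step 0.0001):

overlap% = 100 · ½(|A∩B|/|A| + |A∩B|/|B|),

undefined (reported missing, never 0) if either suprathreshold set is
empty. The null distribution is Monte-Carlo: per iteration, two
independent Gaussian white fields are smoothed to the FWHM estimated from
each observed map, standardized on the mask, and thresholded on the same
sweep. The per-threshold p-value is the plain counting probability
#{null ≥ observed}/n_iter; a protected (k+1)/(n+1) variant is available
(`protected=True`) but the counting rule is the default for fidelity to
the published procedure. Simulated maps are standardized on-mask before
thresholding — an assumption, since p-value thresholds presuppose a
calibrated scale.

**Smoothness estimation**: the map is standardized on the mask; per axis,
the variance of first differences between neighboring in-mask voxels
gives lag-1 autocorrelation ρ = 1 − varΔ/2, and
FWHM = voxel_size · √(−2 ln 2 / ln ρ). For white noise convolved with a
Gaussian kernel this recovers the *kernel* FWHM exactly (verified to
within 2% at 64³); near-white fields are clipped to a small sub-voxel
estimate rather than allowed to diverge.

Directions are analyzed separately (e.g. "controls > group A AND
controls > group B", and the reverse pair), matching the two contrast
pairs of the study design.

## Behavioral PLS

For each block (group × condition) the behavioral columns are z-scored
within block and correlated with each voxel across subjects
(zero-variance voxels get r = 0, counted and logged). Blocks are stacked
row-wise (group-major, then condition, then measure) into R, and
R = U S Vᵀ decomposed. Columns of V are unit-norm brain saliences (one
per voxel, shared across blocks); rows of U are behavior saliences;
sᵢ²/Σsⱼ² is the covariance-explained fraction. Brain scores are the
projection of block-standardized voxel data onto the saliences, computed
per condition.

* **Permutation test**: behavior rows shuffled across subjects — within
  group for the multi-group variant (an open choice; the alternative,
  across groups, can be obtained by fitting the one-group model) — and
  singular values compared *by rank position*, the dominant published
  practice. p is the plain count fraction; with few subjects the
  exhaustive permutation set is used.
* **Bootstrap**: subjects resampled with replacement within group
  (degenerate single-subject blocks redrawn); each resample's saliences
  are aligned to the original by per-LV sign correction (dot-product
  sign), with orthogonal Procrustes rotation available via
  `align="procrustes"`. Without alignment, reflection ambiguity of the
  SVD would corrupt the standard errors. BR = salience / bootstrap SE;
  a voxel with zero salience and zero SE reports BR = 0. Percentile 95%
  CIs are attached to the per-block brain-score/behavior correlations.
* **Display thresholding** (|BR| > 2.5, ≥ 400-voxel 18-connected
  clusters, positive and negative saliences clustered separately) is a
  visualization convention only and enters no inference.

## Effect sizes from summaries

Cohen's d uses the pooled-SD denominator without small-sample (Hedges)
correction — this convention reproduces every parametric effect size in
the reference behavioral table to 2 decimals. The pooled two-sample t
from summaries is algebraically identical to the raw-data pooled t. For
Mann–Whitney rows, z = (U − n₁n₂/2)/√(n₁n₂(N+1)/12) (tie-corrected
variance available via `tie_sizes`), r = |z|/√N, d = 2r/√(1−r²); the
z/√N reading of "r" reproduces the published U = 786 row (d = 0.03) at
n = 38/42.

## MANCOVA

The two-group multivariate test fits responses ~ intercept + group +
covariates and forms the hypothesis and error SSCP matrices for the
group contrast. For a single-df hypothesis the Hotelling–Lawley trace has
the exact transform F = trace · (ν − p + 1)/p with df (p, ν − p + 1),
ν = error df — e.g. 13 responses, n = 80, age + two center dummies gives
F(13, 63). Verified against statsmodels' MANOVA in the tests.

## Synthetic cohorts: what is and is not emulated

`CohortSpec` defaults describe the study conditions: groups of 38
(delay) / 42 (no delay) autistic adults plus 57 neurotypical controls;
ages uniform on 18–41; three scan centers with small additive offsets
(±0.01 map units); behavioral scores on published scales (VIQ 108 ± 14,
F-A-S 37.8 ± 11.2, NWR 21.5 ± 4.2, ADI-R social 18.8 ± 5.2); 4-mm FWHM
smoothing (σ = FWHM/2.3548, periodic convolution so the field is
stationary and the kernel FWHM is exactly recoverable); residual voxel
noise SD 0.05 map units against a smooth brain-like envelope peaking at
0.7 (GM) / 0.6 (WM).

Structure that can be embedded: a multiplicative total-GM offset for the
delay subgroup (default +5%, chosen to land near the reported t ≈ 2 at
n = 80); localized Gaussian-profile group "blobs"; and a per-subject
latent factor z ~ N(0,1) that drives behavioral scores
(score = μ + σ(λz + √(1−λ²)ε), default loadings λ = 0.7 on the three
language measures — a moderate, clearly detectable coupling) and is
expressed spatially as factor × blob pattern.

Two practical consequences of relative-volume scaling are worth knowing
when designing experiments with the generator:

* An *unbalanced* blob changes the subject's total volume, so after
  rescaling it depresses all other voxels and largely cancels at its own
  center. Effects intended as regional redistribution should be
  **volume-balanced** (paired +/− blobs), which is how the test suite and
  acceptance script embed both group effects and latent patterns.
* The delay subgroup's global GM scale cancels exactly in relative maps,
  mirroring the design intent: global and regional effects are separable.

Not emulated: scanner physics, segmentation error, registration
distortion, tissue-boundary geometry, non-Gaussian score distributions
(the generator matches means/SDs only), and spatial nonstationarity.
Passing tests therefore demonstrate correctness and calibration of the
*statistics* under stationary Gaussian conditions, not robustness to
real-data artifacts.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's desk-scale study conditions:

* PLS recovery: n = 80 (38/42), 28³ grid → ≈ 4500 masked voxels, balanced
  GM dipole pattern (amplitude 0.08, radius 10 mm), 500 permutations.
* PLS null calibration: 200 replicate null cohorts × 300 permutations
  (n = 20, 12³ grid), KS test against U(0,1).
* Overlap power: 64³ grid, three groups (25/25/30), shared balanced
  deficit, 1000 null iterations, thresholds 0.05–0.01.
* Overlap null calibration: 32³ grid, 8-mm fields, 400-iteration null,
  150 replicate observed pairs.
* Smoothness recovery: 64³ grid, 4-mm and 8-mm kernels, 10% tolerance.
* Cluster-FDR calibration: 200 null cohorts (n = 24, 16³) × 300
  permutations; observed family rate ≈ 0.04 against the ≤ 0.08 criterion.

The full-protocol settings (5000 overlap iterations, 10 000 permutations
and bootstraps) remain the library defaults.

## Known limitations

* Cluster inference replaces random-field topological FDR with a
  permutation-extent null; under strong nonstationarity the two can rank
  clusters differently. No variance smoothing, TFCE, or voxel-level FWE.
* The smoothness estimator assumes a Gaussian autocorrelation shape.
* The bundled list of 13 canonical language-region centroids is a
  synthetic stand-in (nominal atlas coordinates) for an external
  functional parcellation; it exercises the ROI machinery and is not an
  authoritative region definition.
* Exact p-values for Mann–Whitney rows require raw data and are not
  reported from summaries.
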