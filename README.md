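# langmorph

Structural-brain correlates of individual differences in language within
autism: a tested, reusable implementation of the full analysis chain used
to ask whether autistic adults vary neuroanatomically as a function of
(a) a *history of language delay* (first single words after 24 months or
first phrases after 33 months) and (b) *current structural language
ability* (verbal IQ, F-A-S word generativity, non-word repetition).

The package is aimed at neuroimaging researchers who want these analyses
as composable, seedable library code — with a synthetic-cohort generator
so every stage is testable end-to-end without any MRI download.

## What it computes

**Voxel-based morphometry (VBM) with cluster-level FDR.** Modulated GM/WM
maps are masked at template tissue probability > 0.25 and rescaled by each
subject's total tissue volume ("relative" regional volume). At each voxel
an OLS fit of volume on the binary group indicator plus age (continuous)
and scan center (categorical) gives

&nbsp;&nbsp;&nbsp;&nbsp; *t* = *c*ᵀβ̂ / SE(*c*ᵀβ̂),&nbsp; df = *n* − rank(*X*).

Suprathreshold voxels (one-tailed *P* < 0.025) are clustered by
18-connectivity; each cluster extent *k*ₑ is referred to a permutation
null of the maximum cluster extent (labels permuted within scan-center
strata), and Benjamini–Hochberg FDR over cluster *p*-values yields *q*,
thresholded at *q* < 0.05.

**Conjunction-overlap commonality.** Two one-tailed group-difference maps
are thresholded on a sweep *P* = 0.05 → 0.0001 (step 0.0001); at each
threshold the overlap is 100 · ½(|A∩B|/|A| + |A∩B|/|B|). Significance
comes from a Monte-Carlo null (default 5000 iterations) of independent
Gaussian random fields smoothed to each map's estimated FWHM, with the
plain counting probability *p* = #{null ≥ observed}/*n*.

**Behavioral PLS.** Per block (group × GM/WM condition), the Pearson
correlation of each behavioral measure with each voxel is stacked into
*R* (blocks·measures × voxels); *R* = *U S V*ᵀ extracts latent-variable
pairs. LV *i* explains *s*ᵢ²/Σ*s*ⱼ² of the squared covariance; a
permutation test (default 10 000) on singular values by rank gives LV
*p*-values; bootstrap resampling (default 10 000, within group, with
sign alignment) gives voxel bootstrap ratios BR = salience/SE, displayed
at |BR| > 2.5 with a 400-voxel minimum cluster size.

**ROI replication and summary statistics.** 6-mm-radius sphere ROIs at
published MNI peaks with pooled-variance *t*-tests; MANCOVA
(Hotelling–Lawley trace, exact single-df *F*) over canonical language
regions; Cohen's *d*, pooled *t*, and Mann–Whitney-based equivalent *d*
recomputed directly from printed per-group (n, mean, SD) summaries.

## Worked example

```python
import numpy as np
from langmorph import (CohortSpec, BehavioralPLS, GroupSummary, t_from_summary,
                       cohens_d_from_summary, generate_cohort, relative_cohort_matrix)
from langmorph.cohort import EffectBlob, records_to_table

# Effect sizes straight from printed group summaries
a, b = GroupSummary(38, 33.8, 11.8), GroupSummary(42, 41.3, 10.3)
print("F-A-S Cohen's d =", round(cohens_d_from_summary(a, b), 2))
t, df = t_from_summary(GroupSummary(38, 980, 111), GroupSummary(42, 934, 96))
print(f"total GM: t({df}) = {t:.2f}")

# A synthetic cohort with one embedded latent language factor
spec = CohortSpec(
    n_per_group={"ASC_delay": 38, "ASC_nodelay": 42},
    grid_shape=(28, 28, 28), voxel_size=(2.0, 2.0, 2.0),
    latent_loadings={"VIQ": 0.7, "FAS": 0.7, "NWR": 0.7, "ADIR-S": 0.0},
    latent_spatial_pattern=[EffectBlob((8.0, 8.0, 4.0), 10.0, 0.08, tissue="GM"),
                            EffectBlob((-8.0, -8.0, -4.0), 10.0, -0.08, tissue="GM")],
    seed=42)
records, maps = generate_cohort(spec)
table = records_to_table(records)
gm = relative_cohort_matrix(maps["GM"], "GM")
model = BehavioralPLS({"GM": gm}, table[["VIQ", "FAS", "NWR"]])
res = model.fit()
res.permutation_test(n_perm=500, seed=0)
print(res.summary())
```

Output:

```
F-A-S Cohen's d = 0.68
total GM: t(78) = 1.99
Behavioral PLS
  blocks: 1 group(s) × 1 condition(s) × 3 measure(s)
  LV  singular value  % covariance  perm p
   1         36.5170         96.13  0.0000
   2          5.5217          2.20  0.7000
   3          4.8167          1.67  0.4780
```

The group with a history of language delay is 0.68 pooled-SD below the
no-delay group on word generativity, and its total GM volume is larger at
*t*(78) = 1.99. In the synthetic cohort, the embedded brain–behavior
latent variable is recovered as LV1 (96% of squared covariance, permutation
*p* below 1/500); the remaining LVs are noise.

A command-line interface mirrors the pipeline
(`langmorph simulate | prep | vbm | overlap | pls | roi | report`);
run `langmorph --help`.

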