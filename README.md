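# cliquebars

Topological comparison of weighted functional-connectivity networks.

Resting-state fMRI studies summarise each subject as a correlation matrix
between brain regions — a complete weighted graph.  Classical graph
analysis must binarise such networks at an arbitrary threshold; persistent
homology avoids the choice by analysing *all* thresholds at once.
`cliquebars` implements that pipeline for two-group cohort studies (for
example patients vs controls), from matrices on disk to a statistical
report:

1. **Density clique filtration.**  Edges enter from heaviest to lightest
   weight; each step is re-indexed by the edge density ρ ∈ [0, 1] of the
   thresholded subgraph so that subjects with different weight scales are
   comparable.  The clique complex of each subgraph, truncated at
   triangles, forms the filtration.
2. **Persistent homology** (Z/2): dimension-0 bars track connected
   components (one bar per region, born at ρ = 0), dimension-1 bars track
   cycles.  A barcode is the multiset of [birth, death) intervals.
3. **Persistent entropy.**  Bar lengths l_i (essential bars contribute
   m + 1 − x_i, with m the largest finite death) are normalised to
   p_i = l_i/Σl, and e = −Σ p_i ln p_i summarises each barcode in nats;
   e ≤ ln r with equality for uniform lengths.
4. **Group statistics.**  Pooled bar-length distributions are compared by
   two-sample Kolmogorov–Smirnov tests; per-subject entropies by a
   Lilliefors normality check, a pooled-variance two-sample t-test,
   Cohen's d = |x̄₁−x̄₂|/√((s₁²+s₂²)/2), and an OLS regression
   e = β₀ + β₁·sex + β₂·age + β₃·diagnostic controlling for demographics.

A synthetic-cohort generator produces sample-correlation matrices from a
latent modular factor model (by default at the study conditions: 259
regions, 19 controls vs 24 cases, 500 time points) with a tunable
case-group effect that concentrates the heaviest edges on a few node sets,
lowering both entropies — so the whole pipeline is testable without any
data download.  See `docs/methods.md` for the model details and all
numerical conventions.

## Worked example

```python
from cliquebars import CohortPersistence, CohortSpec

spec = CohortSpec(n_nodes=40, effect=1.0, seed=7)   # synthetic cohort, 19/24
results = CohortPersistence.from_synthetic(spec).fit(max_dim=2)
print(results.summary())
```

```
Cohort persistent-entropy comparison
========================================
subjects: 43 (19 control, 24 case)
config: {'max_dim': 2, 'density_cap': None, 'use_absolute_weights': False, 'lilliefors_mc': 2000, 'stats_seed': 12345}

dimension 0
----------------------------------------
  entropy  control 2.674 +/- 0.008   case 2.626 +/- 0.008
  t = 4.3081  p = 0.0001004  df = 41  Cohen's d = 1.3238
  pooled bar-length KS: D = 0.1740  p = 1.084e-11  sizes = {'control': 760, 'case': 960}
  Lilliefors (MC): control D = 0.1900 p = 0.0650; case D = 0.0925 p = 0.8541
  OLS e0 ~ sex + age + diagnostic (raw scale, n = 43, R^2 = 0.398):
    const      beta = +2.5819  SE = 0.0600  t = +43.016  p = 0.0000
    sex        beta = -0.0145  SE = 0.0112  t = -1.289  p = 0.2049
    age        beta = +0.0064  SE = 0.0038  t = +1.688  p = 0.0993
    diagnostic beta = -0.0469  SE = 0.0109  t = -4.300  p = 0.0001

dimension 1
----------------------------------------
  entropy  control 3.138 +/- 0.041   case 3.008 +/- 0.030
  t = 2.6294  p = 0.01199  df = 41  Cohen's d = 0.7976
  pooled bar-length KS: D = 0.1738  p = 2.858e-09  sizes = {'control': 622, 'case': 718}
  Lilliefors (MC): control D = 0.1531 p = 0.2609; case D = 0.0955 p = 0.8206
  OLS e1 ~ sex + age + diagnostic (raw scale, n = 43, R^2 = 0.148):
    const      beta = +3.0267  SE = 0.2802  t = +10.803  p = 0.0000
    sex        beta = +0.0097  SE = 0.0524  t = +0.184  p = 0.8548
    age        beta = +0.0070  SE = 0.0178  t = +0.393  p = 0.6966
    diagnostic beta = -0.1267  SE = 0.0510  t = -2.486  p = 0.0173

p-values are unadjusted for multiple testing.
```

Reading the report: the case group's persistent entropy is lower in both
dimensions (its bar lengths are less uniform: components merge in a more
concentrated way and it has fewer, shorter cycles), the effect sizes are
large, the pooled bar-length distributions differ (KS), the per-group
entropies are compatible with normality (Lilliefors, so the t-test is
appropriate), and the regression attributes the entropy difference to the
diagnostic label (negative β₃) rather than to sex or age.

## Command line

```bash
cliquebars simulate --out cohort/ --seed 1          # 43 matrices + manifest
cliquebars run --manifest cohort/manifest.csv --out results/
```

`run` writes per-subject barcodes (`barcodes/*.csv`, columns
dim,birth,death with `inf` for essential classes), the per-subject entropy
and bar-count tables, and the group report as both JSON and text.

To analyse a real cohort instead, point the manifest's `matrix_path`
entries at delimited-text correlation matrices (one per subject; comma,
tab or whitespace separated, optional label header row).  The deposited
matrices of the original study (43 adolescent subjects, 259 ROIs) are at
https://doi.org/10.6084/m9.figshare.21941681; after downloading and
preparing a manifest, `python scripts/reproduce_accession.py --manifest …
--out …` runs the identical analysis (expect 1–2 h for 43 × 259-node
subjects on one CPU).

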