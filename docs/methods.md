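# Methods

`cliquebars` compares the topology of two groups of weighted
functional-connectivity networks.  Each subject is a symmetric correlation
matrix over N regions of interest (ROIs); the pipeline turns it into a
density-indexed clique filtration, computes 0- and 1-dimensional persistent
homology, summarises each barcode by its persistent entropy, and compares
the groups statistically.

## Filtration

Given a weighted graph G with off-diagonal weights δ, let
δ_max = δ₁ > δ₂ > … > δ_n = δ_min be the distinct weights in decreasing
order.  Thresholding at δ_i keeps every edge with weight ≥ δ_i, producing a
nested sequence of subgraphs that starts from the bare vertex set and ends
at G.  Each step is re-indexed by its *edge density* ρ_i — the fraction of
G's edges present — so that networks with different weight scales share the
common filtration coordinate ρ ∈ [0, 1].  Tied weights enter together, so
ρ can jump by more than 1/|E| in one step.  The clique complex of each
subgraph (every complete subgraph is a simplex), truncated at triangles,
gives the clique filtration fed to homology.  Truncation at dimension 2 is
exact for H₀ and H₁ and keeps the complex size at
N + C(N,2) + C(N,3) (≈ 2.9 M simplices at N = 259).

Two consequences used throughout:

* **Monotone invariance.**  Only the descending rank of the weights enters,
  so any strictly increasing transform of the weights leaves the filtration
  — and everything downstream — unchanged.
* **Density denominator.**  The density is computed against the network's
  own edge count; a correlation matrix is a complete graph, so the
  denominator is N(N−1)/2.

Negative correlations are kept and ordered by signed value (they enter
last); ranking by |weight| is available behind `use_absolute_weights` but
off by default, since discarding or rectifying negatives is a modelling
decision the pipeline should not make silently.  A `density_cap` can
truncate the filtration for speed; it changes results (features that would
die above the cap become essential) and is therefore off by default.

## Persistent homology

Computation is the standard boundary-matrix column reduction over Z/2, run
sparsely with the *clearing* optimisation: triangle columns are reduced
first in filtration order, and every edge claimed as a pivot there is known
to be cycle-creating, so its own column is skipped in the edge reduction.
For the large triangle reduction a numba kernel operates on sorted int64
index arrays; small inputs use an equivalent pure-Python path (both are
tested against each other and against a naive dense reduction).  Dimension
0 is additionally computed by an independent union-find sweep with the
elder rule (all components are born at ρ = 0, so the merge tie-break is the
smaller representative vertex index); the two dim-0 routes must agree
exactly and both are exercised in the tests.

Ties in appearance are resolved by (dimension, vertex tuple) before
reduction; the resulting pairs with equal birth and death density are
zero-persistence artifacts of the tie ordering and are dropped.  Every
vertex yields a dim-0 bar, so the dim-0 bar count always equals N; a
complete network is connected, leaving exactly one essential dim-0 bar and
no essential dim-1 bars.

## Persistent entropy

For a barcode with bars [x_i, y_i), the lengths are l_i = y_i − x_i for
finite bars and l_i = m + 1 − x_i for essential bars, with m the largest
finite death.  With p_i = l_i / Σl, the persistent entropy is
e = −Σ p_i ln p_i, in nats.  It is bounded by ln r (r the bar count), with
equality exactly for uniform lengths, and is invariant under rescaling all
lengths.  When a barcode has no finite death at all (edgeless or
single-vertex degenerate inputs), m falls back to the largest birth, which
keeps all lengths positive; real correlation networks never hit this path.
Natural logarithms are used throughout (ln 259 ≈ 5.56 bounds the dim-0
entropy of a 259-ROI subject).

## Group statistics

Four pooled bar-length multisets (group × dimension) are compared with a
two-sided two-sample Kolmogorov–Smirnov test; D is computed from the two
ECDFs and the p-value from the Smirnov asymptotic null at effective size
n₁n₂/(n₁+n₂) (the variant scipy uses; finite-size corrections used by some
other implementations differ negligibly at pooled sizes in the thousands).
Per-subject entropies are checked for normality per group with a Lilliefors
test: the distance is the KS distance to the normal with estimated mean and
(n−1)-SD, and the p-value is a seeded Monte-Carlo estimate (2 000 null
samples by default, add-one estimator), the method being recorded in the
report.  The group comparison is a pooled-variance two-sample t-test with
Cohen's d = |x̄₁ − x̄₂| / √((s₁² + s₂²)/2) on sample SDs, plus group means
with standard errors.  All p-values are reported unadjusted and labelled
as such.

A covariate regression e_dim = β₀ + β₁·sex + β₂·age + β₃·diagnostic (sex
0 = male, 1 = female; diagnostic 0 = control, 1 = case) is fitted by OLS via
statsmodels on complete cases.  Both a raw-scale fit and a min-max-scaled
fit (response and age scaled to [0, 1]) are reported: scaling is affine, so
t statistics and p-values are identical between the two and only the
coefficient magnitudes change.  Conclusions should rest on the sign and
significance of β₃, not on coefficient magnitudes, which depend entirely on
the scaling convention chosen.

## Synthetic cohorts

The generator produces the study conditions by default: 259-node matrices,
19 controls and 24 cases, ages 13–17, sex assigned independently of group
(p(female) = 15/43).  A subject's matrix is the *sample* correlation of
T = 500 multivariate-normal draws — matching the volume count of a
six-minute multiband scan — from a latent factor model: a global factor
sets the between-module level (r_between = 0.05), one factor per module
(8 modules) sets within-module coherence (r_within = 0.35).  The factor
construction guarantees a positive-semidefinite latent covariance; a
residual-variance check rejects impossible loadings.

Because the pipeline only sees weight ranks, the case group is manipulated
through the ranking structure: round(16·effect) disjoint *strong pairs* and
round(1·effect) *hub cliques* of 6 nodes receive a shared factor with
loading 0.55, concentrating the heaviest edges on a few node sets.  Pair
and hub members merge almost immediately (a sharp peak of very short dim-0
bars, lowering e₀), and hub cliques fill their own cycles with triangles as
soon as they form (fewer and shorter dim-1 bars, lowering e₁ and the
per-subject hole count).  At effect = 0 the groups are exchangeable by
construction.  The default effect = 1.0 is the documented calibration
point: at 40-node test scale with 19/24 subjects, the dim-0 entropy t-test
holds its nominal 5% size under the null (5/100 in the calibration run) and
rejects in ≳ 95% of replicates at effect = 1.0, with case-group means of
e₀ and e₁ both below control — the qualitative pattern the pipeline is
meant to detect.

What the generator does *not* emulate: hemodynamics, motion and
preprocessing artifacts, spatial autocorrelation of real parcellations,
inter-subject variability in module layout, and any empirical marginal
distribution of real correlations.  Passing tests therefore demonstrate
that the pipeline detects rank-structure differences of the designed kind
at realistic noise levels — not that real ISAD and control cohorts differ.

## Numerical choices and problem sizes

* Coefficients over Z/2; elder-rule ties broken by smallest vertex index
  (entropy is invariant to this choice — lengths are unaffected).
* Matrix reads tolerate asymmetry only up to 1e-12 unless `symmetrize` is
  requested explicitly; the diagonal is always discarded.
* Reports serialise floats at 12 significant digits for cross-platform
  diffability.
* Test problem sizes: random-graph oracle battery at N ≤ 20 (200 graphs);
  statistical calibration at N = 40 nodes with the study's 19/24 group
  sizes (200 null replicates, 100 powered replicates); full-scale checks at
  N = 259.  A complete 259-node subject (2.9 M triangles) takes tens of
  seconds for both homology dimensions; dimension 0 alone takes seconds.

## Known limitations

* Homology stops at dimension 1; persistence landscapes, images and
  bottleneck distances are out of scope.
* The Lilliefors p-value is Monte-Carlo, so it carries sampling error of
  order 1/√2000 ≈ 0.02; the distance D is exact.
* The regression's coefficient magnitudes depend on an arbitrary scaling
  convention (see above); only β₃'s sign and significance are meaningful
  deliverables.
* With a `density_cap` set, essential dim-1 classes appear whose entropy
  contribution depends on the cap; capped runs are not comparable with
  uncapped ones.
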