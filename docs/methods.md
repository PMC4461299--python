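# Methods

## Simulation model

Each simulated dataset is a genes × samples matrix with two groups.  For
gene *g* and sample *j*:

- control group: x ~ N(μ₀, σ²) for every gene;
- treatment group: x ~ N(μ₀, σ²) for null genes, N(μ_up, σ²) for
  up-shifted genes, N(μ_down, σ²) for down-shifted genes.

Defaults: 2,000 genes, 37 up + 36 down shifted, μ₀ = 10, σ = 1.3, and two
presets for the shifts — `dataset1` (15 / 5, i.e. ±3.85 σ) and `dataset2`
(13.5 / 6.5, ±2.7 σ).  All values are treated as already log-like (post-
normalization log₂ intensities sit in exactly this range), so group-mean
*differences* play the role of log fold changes and "fold change 2" means
|Δ̄| ≥ 1.

Replicate structure: each gene carries `n_samples_per_group = 10` values
per group.  This is a package choice — a benchmark element must offer the
detectors something to estimate variance from, and 10 per group is a
realistic medium-sized microarray comparison.  Results that depend on the
*error* side of detection (false-positive counts, the Bland–Altman miss
rate) are sensitive to this choice; results on the *signal* side (recall
of ±2.7–3.85 σ shifts) are not, and those are the quantities the package
pins down.  Gene order is shuffled so shifted genes are not positionally
clustered; identifiers are zero-padded (`g000001` …) and the truth labels
are written alongside every simulated matrix for audit.

What the generator does **not** emulate: probe-level effects, array batch
effects, intensity-dependent variance, correlation between genes.  Every
gene is independent with a common σ, so passing this benchmark shows a
detector handles well-behaved shifted means — not that it survives real
microarray artefacts.

## Detectors

All six consume the same two-group matrix and emit one record per gene:
statistic, p-value (where defined), fold change Δ̄ = mean(treatment) −
mean(control), direction, and a binary call.

**TT** — two-sample t-test, Welch's unequal-variance form by default
(pooled form behind a flag), two-sided, called at raw p < 0.01.  Genes
constant and identical in both groups get t = 0, p = 1.

**MW** — Mann–Whitney rank sum, two-sided.  Exact null enumeration when
both groups have ≤ 8 samples and the gene has no ties; otherwise the
normal approximation with tie and continuity correction.  All-tied genes
get p = 1.  Called at raw p < 0.05.

**LIMMA** — moderated t.  Per-gene residual variance s² on d = n₁+n₂−2
degrees of freedom; hyperparameters (d₀, s₀²) of the scaled
inverse-chi-square prior estimated by matching the mean and variance of
log s² to their theoretical values (digamma/trigamma moment matching; the
trigamma inverse is solved by Newton iteration).  Posterior variance
s̃² = (d₀s₀² + d·s²)/(d₀+d); t = Δ̄/(s̃·√(1/n₁+1/n₂)) on d₀+d df; called at
p < 0.05.  When the observed log-variance spread does not exceed
chi-square sampling noise the prior degenerates to d₀ = ∞ and the
statistic uses the ordinary pooled (arithmetic-mean) variance for every
gene — chosen so that squeezing an exactly-constant variance ensemble
changes nothing.

**SAM** — relative difference d = Δ̄/(s + s₀) with s the pooled standard
error.  s₀ is picked from the 0th–100th percentiles (step 5) of {s} to
minimize the coefficient of variation of windowed MADs of d across
s-quantile windows (100 windows, fewer for small gene sets).  The null
comes from group-label permutations (200 by default; all label
assignments enumerated with a warning when fewer exist), **pooled across
genes**: p_g = (1 + #{|d*| ≥ |d_g|})/(1 + G·B).  Pooling is what gives a
permutation test resolution below 1/B; the attainable floor is
1/(G·B + 1).  Calls require Benjamini–Hochberg q ≤ 0.05 **and**
|Δ̄| ≥ log₂(fold-change threshold).  Both the q threshold and the
fold-change scale (`log2` vs `linear` ratio) are configurable.

**RP** — rank product.  For each of the K = n₁·n₂ treatment/control
sample pairs, pairwise differences are ranked across genes (rank 1 = most
up-regulated for the up search, most down-regulated for the down search);
RP_g is the geometric mean of its ranks.  The null assigns each
comparison an independent uniform random permutation of ranks, B = 100
rounds, pooled over genes; each direction gets a p-value and a
percentage-of-false-prediction column, and a gene is called when its
better direction has p < 0.01.

**BA** — Bland–Altman across genes: with m and s the mean and SD of the
per-gene differences Δ̄ over all genes, z_g = (Δ̄_g − m)/s is referred to
the standard normal; called at two-sided p < 0.02, i.e. outside the
limits of agreement m ± z₀.₉₉·s.  Zero spread (s = 0) yields no calls and
a logged warning.

No multiple-testing correction is applied to TT/MW/LIMMA/RP by default:
the benchmark's fixed thresholds are raw per-gene levels, and its
false-positive counts are only consistent with raw thresholding.

## Scoring

The positive class is "truth label ≠ none", direction-agnostic by default;
a strict mode additionally requires the called direction to match (a
wrong-direction call then counts as a miss, keeping TP+TN+FP+FN equal to
the gene count).  Metrics: acc = (TP+TN)/N, rec = TP/(TP+FN), prec =
TP/(TP+FP), fm = 2TP/(2TP+FP+FN), and MCC with the standard formula and
the 0-with-flag convention for degenerate marginals.  Undefined metrics
raise rather than silently returning 0.  Tables are stored at full
precision; a display option truncates (not rounds) to 3 decimals.

The overall score tiers methods per dataset: 3 points for best (or tied)
on ≥ 3 of the 5 measures, 0 for worst on ≥ 3, 2 for best on ≥ 1 or within
0.02 of best on ≥ 3, else 1; the 0-tier is checked before the 2-tier so a
method that is worst nearly everywhere cannot ride a single tied-best
measure.  The tiering is a convention for summarizing the metric table,
not a canonical statistic, and is configurable.

## Seeds and determinism

One master seed fans out through counter-based `SeedSequence` spawn keys:
per-dataset (and per-replicate) simulation seeds, and per-method
permutation streams keyed by method index — adding a method or dataset
never perturbs the others' draws.  Identical configuration and seed give
byte-identical outputs; derived integer seeds stay below 2³¹.

## Known limitations

- **RP's independence assumption.**  With replicated groups the K sample
  pairs share samples, so a null gene's ranks are correlated across
  comparisons; the canonical independent-rank null then understates the
  null spread of rank products and RP over-calls at raw p < 0.01 (hundreds
  of false positives at 10 samples/group).  Its recall is unaffected.
- **BA's sensitivity to replicate count.**  The limits of agreement are
  set by the across-gene spread of mean differences, which shrinks with
  √n per group; at 10 samples/group even the ±2.7 σ shifts sit ~4 spreads
  out and BA misses little, while with one value per group the same
  shifts sit inside the limits and BA misses a substantial fraction.
- **Discrete and conservative sizes.**  At 10 samples/group the rank-sum
  test's exact size at nominal 0.05 is 0.0433 (discreteness), and Welch's
  t at nominal 0.01 attains ~0.0094 (random Satterthwaite df); the
  calibration tests compare against these attained sizes, not the nominal
  levels.
- Two groups only; no paired designs, covariates, or multi-class layouts.
- The class-summary "separation" statements refer to quartile boxes; true
  extremes of thousands of normal draws always overlap adjacent classes.

## Problem sizes used in tests

The default suite simulates 2,000-gene matrices for the benchmark-scale
checks, 200 clean replicates for null calibration, 500 shifted genes per
level for power monotonicity, and exhaustive enumeration oracles up to 6
samples per group (rank-sum) and C(4,2) label assignments (permutation
tests) — sizes at which the exact oracles are cheap and the stochastic
assertions have comfortable margins.
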