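# Methods

## Model

For a putative virus–host pair observed at a set of sampling sites, let
*x* be the host relative abundance and *y* the virus relative abundance
(both dimensionless proxies for density; the package applies no
normalization of its own). A power-law relationship *y* ∼ *x*^α is linear
on log axes, so α is estimated as the ordinary least-squares slope of
log₁₀ *y* on log₁₀ *x*. The ratio regression of log₁₀(*y*/*x*) on
log₁₀ *x* has slope β satisfying the algebraic identity β = α − 1 (the
ratio regression subtracts *x*'s own log from the response, shifting the
slope by exactly −1). Two consequences anchor the analysis:

- sublinear coupling (0 < α < 1) implies −1 < β < 0;
- *independence* (α = 0) implies β = −1, because the ratio fit collapses
  to regressing 1/*x* on *x*. A ratio slope near −1 is therefore evidence
  of *no* virus–host relationship, not of sublinear scaling. This is
  spurious self-correlation, and the package treats E[β̂] = −1 under
  independence as its operational statement, verified by Monte-Carlo with
  a four-standard-error tolerance.

The implementation computes β̂ by its own regression of
log₁₀ *y* − log₁₀ *x* on log₁₀ *x* rather than via the identity, so
β̂ = α̂ − 1 remains a genuine cross-check (asserted to 10⁻¹⁰ relative
tolerance in the test suite).

## Inference

Significance of each pair's relationship is assessed by a randomized
permutation test: the virus vector is shuffled uniformly at random
(independent shuffles, not guaranteed-distinct permutations — standard
Monte-Carlo practice, indistinguishable from distinct sampling at the
site counts involved) while the host vector stays fixed, and the
statistic is recomputed per shuffle. The default statistic is the log–log
OLS slope; Pearson *r*, average-rank Spearman ρ and the Theil–Sen median
pairwise slope are also available. Slope and Pearson *r* give identical
permutation p-values because slope = *r*·sd(*y*)/sd(*x*) with both
standard deviations permutation-invariant; the suite asserts the
equality.

The two-tailed p-value uses the add-one convention

&nbsp;&nbsp;&nbsp;&nbsp; p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm),

which cannot return 0 from finite resampling. The exceedance comparison
applies a 10⁻¹² relative tolerance so that permutations that tie the
observed value exactly (e.g. the identity shuffle) count as exceedances
even when a different BLAS summation order perturbs the last bit. The
95% randomized CI is the (2.5, 50, 97.5) percentile triple of the null
values, computed with numpy's linear-interpolation percentile definition
(frozen here so CI values are reproducible). An exhaustive n!-enumeration
oracle (n ≤ 8) backs the Monte-Carlo machinery in tests.

Randomness: one master seed; each pair's shuffles come from a substream
keyed by `(seed, crc32(pair_id))`, and each synthetic pair from
`(seed, pair_index)`, so per-pair results do not shift when other pairs
are added or removed, and identical inputs give bitwise-identical
outputs.

## Multiple testing

Per-pair flags are reported at 0.05 and 0.01, plus a Bonferroni criterion
pooling the genus- and phylum-level families into one family: threshold =
family α / m with m = all pairs tested (for a 48 + 16 family at α = 0.05,
0.05/64 = 0.00078 at two significant figures, the display convention).
Significance uses strict inequality p < threshold; with the add-one
p-value convention exact ties are effectively measure-zero. A per-level
correction is deliberately not the default. FDR control is out of scope.

## Filtering

Sites where either abundance is zero are removed jointly (paired log-scale
statistics need paired positivity), and pairs with fewer than
`min_sites = 5` positive sites are excluded. Five is a study convention,
not a mathematical requirement, so it is configurable with a hard floor
of 2 (below which no slope exists). Filtering is idempotent, order- and
value-preserving.

## Synthetic data generator

`SyntheticConfig` defaults define the simulated study conditions:
39 sites per pair (matching the cross-site tables the package targets),
host log₁₀-abundances Normal(−3, 1) — lognormal abundances with a spread
of a few decades, typical of relative-abundance data — virus abundances
10^(α·log₁₀x + intercept + e) with e ∼ Normal(0, noise_sd), noise sd 0.5
in log₁₀ units (about a factor-of-three scatter), and optional
zero-inflation by independent random masking of each abundance at rate
`zero_rate`. Masking rather than detection-limit truncation is a
deliberate simplification: it exercises the exact filtering rule
regardless of the censoring mechanism.

What the generator does *not* emulate: compositional closure (abundances
are not renormalized to sum to one, so the compositional artifacts of
relative-abundance data are absent), cross-pair dependence (pairs are
independent), spatial/temporal autocorrelation between sites, and any
mechanistic virus–host dynamics. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated on an idealized lognormal
world; they do not show that real metagenomic tables satisfy those
assumptions.

## Numerical choices and degenerate inputs

- log₁₀ throughout; slopes are invariant to the log base and log₁₀
  matches abundance-plot axes.
- Constant virus vector: the least-squares solution is the flat line, so
  α̂ = 0 is returned (keeping the β = −1 degenerate case computable) with
  the correlations reported as NaN rather than a fabricated 0; the
  correlation-based permutation tests refuse such data as degenerate.
- Constant host vector: degenerate for every statistic (error).
- Spearman uses average ranks for ties — relative-abundance data can tie
  at detection limits.
- Theil–Sen skips point pairs with equal host values; if all are skipped
  the estimate is a degenerate-fit error. The "nonparametric slope" is
  realized as Theil–Sen (with Spearman as the nonparametric correlation);
  other conventions exist, and the choice is stated here because it is a
  design decision, not a forced one.
- The ratio fit is assumed to be OLS, the default reading of a best-fit
  line on log–log axes.

## Problem sizes

Defaults for the simulation experiments: 1000 replicates for the null
ratio-slope experiment; 500 pairs × 2000 permutations for the type-I
error calibration (2000 permutations resolve a 0.05 rejection decision
comfortably; the per-pair analyses themselves default to 10⁴
permutations). The acceptance script runs both in a few seconds because
the permutation nulls are computed by vectorized closed forms (centered
dot products against the fixed host vector).

## Known limitations

- Relative abundances are taken at face value; no compositional
  correction is applied, and spurious correlation induced by closure is
  outside the scope of the permutation null.
- Inference is purely by permutation; no analytic (t-based) p-values,
  errors-in-variables or reduced-major-axis slopes, or bootstrap CIs of
  the observed slope (the reported CIs describe the *null*, not the
  estimate).
- Near the 0.05 boundary, significance counts on real data can shift by a
  pair across RNG seeds; the per-pair seed substreams make any such shift
  reproducible.
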