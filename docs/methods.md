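# Methods

## Model

Phenotype records from a multi-environment trial are modeled at the line
level as

    y = μ1 + u + e,    u ~ N(0, σ_u² K),    e ~ N(0, σ_e² I)

where K is an n × n genomic kernel over lines and heritability is
h² = σ_u²/(σ_u² + σ_e²). Two routes turn this into a prediction machine:

1. **Kernel square root.** K^{1/2} = V diag(√λ) V′ is used as a feature
   matrix: the design seen by an arbitrary learner is Z K^{1/2}, with Z the
   N × n observation-to-line incidence matrix. Training a ridge-type
   learner on this design is kernel regression with K.
2. **Sparse (Nyström) design.** With m anchor lines, K ≈ Q =
   K_nm K_mm⁻¹ K_nm′. Eigendecomposing K_mm = U S U′ gives the projected
   design P = K_nm U S^{−1/2} with P P′ = Q, so model (above) becomes
   y = μ1 + Pf + ε with f ~ N(0, σ_f² I) of length m — m effects instead
   of n, usable by any learner as a fixed-effect design.

## Kernels

All kernels act on centered/scaled markers (sample sd, n−1 denominator;
zero-variance markers dropped with their identities logged; fitted
constants retained so new lines transform identically).

| kernel | formula | defaults |
| --- | --- | --- |
| linear | x·z / p | — |
| polynomial | (γ x·z + c₀)^d | γ = 1/p, d = 3, c₀ = 0 |
| sigmoid | tanh(γ x·z + c₀) | γ = 1/p, c₀ = 0 |
| gaussian | exp(−γ ‖x−z‖²/s) | γ = 1, s = median heuristic |
| exponential | exp(−γ ‖x−z‖/√s) | γ = 1, s = median heuristic |
| arc-cosine depth L | recursion on k₁(x,z) = (1/π)‖x‖‖z‖(sin θ + (π−θ)cos θ) | L = 1 |

Numerical conventions:

- **Bandwidth.** The gaussian/exponential squared distances are divided by
  s, the median nonzero pairwise squared distance of the reference set,
  before γ applies; this keeps γ dimensionless across marker densities
  (set `distance_scale=1` for the raw form). Cross-kernels reuse the
  anchor/reference set's s so K_nm and K_mm share a scale. Because γ
  already absorbs the bandwidth through s, its default is 1 for these two
  families, while polynomial/sigmoid keep the 1/p convention.
- **Arc-cosine.** The arccos argument is clamped to [−1, 1]; zero-norm rows
  yield kernel value 0 by convention. The depth-1 transform leaves the
  diagonal invariant, so self-values are ‖x‖² at every depth.
- **Square root.** Eigenvalues below 1e-10·λ_max — including all negatives,
  which the indefinite sigmoid kernel produces — are clamped to zero; a
  warning fires when the clamped mass exceeds 1% of the trace.
- **Nyström truncation.** K_mm is inverted through its eigendecomposition
  with the same relative cutoff (a pseudo-inverse rather than a literal
  inverse), so rank-deficient anchor sets are usable; the retained rank
  r ≤ m is reported alongside m. For the sigmoid kernel this means the
  approximation targets the PSD part of K_mm — the only consistent choice
  once S^{−1/2} must be real.
- **Anchors** are m = ceil((1 − compression)·n) lines drawn uniformly
  without replacement at the line level (replicated lines across
  environments stay coherent), seeded and reproducible. When a precomputed
  kernel is supplied, K_mm and K_nm are sliced from it.

## Bayesian samplers

`fit_brr` and `fit_gblup` are conjugate Gibbs samplers (defaults: 1500
iterations, 500 burn-in, thin 1, all draws seeded through
`numpy.random.default_rng`).

- **BRR**: y = μ1 + Xβ + e with β_j ~ N(0, σ_β²) iid. The coefficient
  block is rotated into the SVD basis of X, where its full conditional is
  diagonal — O(min(n,p)) per sweep after one SVD. Null-space coefficients
  have the prior as full conditional; only their sum of squares enters the
  variance update and is drawn as one chi-square variate.
- **GBLUP**: u = Γδ with Γ the eigenvectors of K (spectrum truncated at
  1e-10·λ_max), so δ has independent prior components N(0, σ_u²λ_i). When
  Z′Z is a multiple of the identity (balanced replication — e.g. every
  line in every environment, or one record per line) the δ-update is
  diagonal; otherwise a dense Cholesky update of order r is used.
- **Priors**: scaled-inverse-χ² with df 5 on both variance components, the
  scale set so each term explains half the phenotypic variance a priori
  (mode at 0.5·var(y), divided by the mean kernel diagonal or the summed
  marker variance so the genetic term is on the right scale). These mirror
  the common convention of Bayesian genomic-prediction software.
- With K = XX′/p on centered/scaled markers, BRR and GBLUP are the same
  model in different parameterizations; the acceptance run verifies
  prediction correlation > 0.99 between the two samplers.
- Heritability is reported as the posterior mean of the per-draw ratio
  σ_u²/(σ_u² + σ_e²). In the recovery experiments environment main
  effects are removed by centering the trait within environment before
  fitting — GBLUP as implemented has no environment term, and per-
  environment centering is the standard pre-adjustment.
- Binary/categorical responses are out of scope for the samplers
  (continuous only); counts are treated as continuous with a warning.

## Tuning

Grid search evaluates the full Cartesian product of discrete value lists
under seeded inner k-fold CV (K = 5 by default); the winner is the
minimal mean fold loss, ties broken by enumeration order, and requires at
least one dimension with ≥ 2 values. Bayesian optimization evaluates 5
seeded Sobol points, then 10 iterations (defaults) of: fit a GP
(Matérn-5/2 + white noise, standardized losses) to the evaluations,
maximize expected improvement over a seeded 512-point candidate set,
evaluate. The surrogate and acquisition are this package's choices —
established convention, since only the method and its 10-iteration budget
are fixed by the interface. Integer hyperparameters are optimized on a
continuous relaxation and rounded at evaluation. Tuning loss defaults to
MSE for continuous responses and log-loss for classes (accuracy by flag).
Inner folds are drawn from the outer-training rows only; the no-leakage
guard (nested CV on pure noise does not beat the intercept baseline) is
part of the test suite.

## Metrics

MAAPE's undefined y = 0 case contributes the arctan limit π/2 (count
logged). NRMSE defaults to sd normalization (sample sd); mean
normalization uses the signed mean and errors on zero. Multiclass derived
metrics are macro-averaged; ROC-AUC/PR-AUC are one-vs-rest macro; the
multiclass Brier score is the mean squared Euclidean distance between
probability vectors and the one-hot truth (range [0, 2]); AUC ties are
handled by midrank. For binary problems the positive class is the first
sorted level.

Benchmark summaries: every metric is computed per (environment, fold)
cell; environment rows are mean and SE = sd/√(folds) over folds; Global
pools all environments within each fold before computing the metric, then
averages over folds (an average-of-environment-means mode is available by
flag but non-default, matching the convention that Global is the average
of the test partitions). Partitions are stratified by environment so each
environment appears in every test set. Percent outperformance is
100·(MSE_ref − MSE_better)/MSE_ref **truncated** to 2 decimals — the
truncation (rather than rounding) reproduces the published comparison
values exactly; a complementary `percent_relative_excess` normalizes by
the better model's MSE.

## Synthetic data

The generator emulates a multi-environment breeding trial: biallelic SNP
dosages ~ Binomial(2, q) with q ~ Uniform(maf_range) per marker
(Hardy–Weinberg, no linkage disequilibrium; monomorphic columns
resampled); additive genetic values g = X_s β, β ~ N(0, 1/p), with an
epistatic option adding pairwise products of a random 1% marker subset;
g rescaled to variance σ_u² = h² and residuals N(0, 1 − h²) per record;
environment main effects N(0, env_effect_sd²); one record per
line × environment. Defaults (300 lines × 500 markers × 4 environments,
h² = 0.5, MAF 0.05–0.5) are a desk-scale analogue of public wheat/maize
trial data. What it does *not* emulate: linkage disequilibrium, population
structure, genotype × environment interaction, missing data. Tests passing
on these simulations therefore validate the algorithms and their
contracts, not performance on structured real populations.

## Problem sizes in the verification experiments

The package's own experiments use sizes chosen to make the statistical
properties sharp at desk scale: equivalence runs at 150 lines × 300
markers (5 seeds); heritability recovery at 300 lines × 4 environments
(10 seeds per h²); compression retention at 200 lines with a gaussian
kernel, compression 0.5, fixed ridge penalty (10 seeds); Nyström oracle
checks at n ≤ 30 across all kernel families. The gaussian kernel is used
for the retention experiment because its fast-decaying spectrum is the
representative favourable case for Nyström compression; heavier-tailed
kernels (e.g. arc-cosine) retain less accuracy at the same compression
unless the ridge penalty is retuned — a known limitation.

## Known limitations

- The sigmoid kernel is not PSD; everything downstream operates on its
  clamped PSD part.
- The Bayesian samplers are univariate and continuous-response only.
- Anchor selection is uniform; leverage-score or k-means selection is out
  of scope.
- The feed-forward `neural_network` learner is a basic single-hidden-layer
  wrapper, not a configurable deep-learning stack.
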