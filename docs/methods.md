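# Methods

## The model

`mcip` clusters `n` genes from an `N x n` (samples x genes) expression
matrix `D`, guided by pairwise prior knowledge. A clustering is a
*grouping* `g = (g_1, ..., g_n)`, `g_i ∈ {1..K}`; labels are exchangeable
and always stored canonically (relabelled by order of first appearance).
Inference targets the posterior `P(g | D, M) ∝ P(D | g) P(g | M)` where
`M = {(i_m, j_m, p_m)}` is a set of `q` prior pairs, `p_m` being the
probability that pair `m` is *forced* into one group.

### Marginal likelihood

Within a group of `n_k` genes, the standardised expression rows are
modelled as zero-mean multivariate normal with covariance `Σ_k`, and
`Σ_k ~ InverseWishart(Ψ_k, m_k)` with `Ψ_k = ρ_k I` and `m_k = n_k + 2`
(the smallest degrees of freedom for which `E[Σ_k]` exists; with
`ρ_k = 1` that expectation is the identity, encoding unit variances after
standardisation). Groups are independent, and the covariance integrates
out in closed form:

    log P(X_k) = (m_k/2) log|Ψ_k| + log Γ_{n_k}((m_k+N)/2)
                 − (N n_k/2) log π − ((m_k+N)/2) log|Ψ_k + X_kᵀX_k|
                 − log Γ_{n_k}(m_k/2).

`Ψ_k + X_kᵀX_k` is positive definite even when `n_k > N`, so wide groups
evaluate safely. Standardisation (per-gene mean 0, variance 1, `N−1`
denominator; the choice of denominator is immaterial to ranking at
realistic `N`) is enforced because the model has no mean parameter.
Per-group terms are cached by frozen member set: an MCMC move touches at
most two groups, so a step costs O(group size³), not O(n³).

### Partition prior with pairwise enforcement

The number of partitions of `n` items into `K` groups satisfies
`N(n,K) = K·N(n−1,K) + N(n−1,K−1)`, `N(K,K) = 1` (Stirling numbers of the
second kind); all counts are kept in log space (`N(100, K)` far exceeds
float integer range). The *baseline prior* is uniform over `K` and
uniform over groupings given `K`: `P(g|M_0) = 1/(n·N(n,K_g))`. Under it,
two arbitrary genes are co-grouped with probability
`P_b = (1/n) Σ_K N(n−1,K)/N(n,K)` — 0.25 at n=10, 0.048 at n=100.

With priors, each enforcement mask `X ∈ {0,1}^q` (with `x` ones) merges
the genes into `n − x` units and applies the baseline measure there:

    P(g|M) = Σ_X Π_m p_m^{X_m}(1−p_m)^{1−X_m}
             · I(K_g ≤ n−x, enforced pairs co-grouped) / ((n−x) N(n−x, K_g)).

The `n − x` unit count silently assumes the enforced edges never close a
cycle, so the pair set is first reduced to a maximum-weight spanning
forest (Kruskal on decreasing `p`, ties broken in stable input order):
within a cycle, the weakest pair is read as implied by the others.
Exact evaluation factors pairs split by `g` out of the sum (they
contribute `1 − p_m` deterministically) and enumerates masks only over
co-grouped pairs, refusing beyond 20 of them. Past that, a Monte-Carlo
estimator draws masks from the Bernoulli prior over the co-grouped pairs
and averages `I(K_g ≤ n−x)/((n−x)N(n−x,K_g))`; it is unbiased on the
probability scale, exact (zero variance) when no prior pair is
co-grouped, and uses 200 draws by default. Probabilities of exactly 1
are clamped to `1 − 1e−12` so mixture weights never hit `log 0`; a hard
constraint is better expressed by pre-merging genes.

The indicator is read as `K_g ≤ n−x` (the source prints both `<` and
`≤`; the single-pair `p = 1` derivation requires `≤`).

### Sampling

Metropolis–Hastings over partitions with three moves, each probability
1/3 when admissible (split impossible at `K = n`, merge and move at
`K = 1`, move also at `K = n`):

* split: group chosen with probability `n_k/(n−n_s)` among non-singletons
  (`n_s` = singleton count), then one of the `N(n_k,2) = 2^{n_k−1}−1`
  unordered bipartitions uniformly;
* merge: `Q = (n_k/n)(n_l/(n−n_k)) + (n_l/n)(n_k/(n−n_l))` times the
  move-type probability (either gene-sampling order);
* move: `Q = n_k/((n−n_s)(n−n_l)) · 1/3` for moving a uniformly chosen
  member of a non-singleton group `l` into group `k`.

Split and merge reverse each other; a move reverses itself. Acceptance is
`min(1, [posterior ratio]^β · Q(g|g′)/Q(g′|g))`. On instances small
enough to enumerate, the empirical chain distribution matches the exact
posterior (total variation < 0.05 at 2×10⁵ iterations) and the full
kernel satisfies detailed balance to 1e−8 — the primary correctness
surface of the package.

When the prior is estimated by Monte Carlo, *fresh* estimates are drawn
for both the current and proposed state at every step; estimator
variance shrinks as 1/draws and can be reduced via `mc_prior_samples`.

Parallel tempering runs chains at inverse temperatures `β_i = r^i`
(default 4 chains, ratio 0.7), tempering likelihood and prior together;
after each sweep one uniformly chosen adjacent pair attempts a state swap
accepted with `min(1, exp((β_i−β_j)(log π_j − log π_i)))`. With one
temperature this reduces exactly to the plain chain. The ladder and swap
schedule are this package's own design; so is the initial state, drawn
from the baseline prior (uniform `K`, then a uniform partition with `K`
groups by sequential placement using the count recursion).

### Summarising samples

The posterior similarity matrix (PSM) holds co-clustering proportions
`p_ij` over the thinned post-burn-in samples. Candidate partitions for
`K = 1..L` (default `L = 30`) come from agglomerative clustering on the
dissimilarity `1 − p` (average linkage by default, complete available)
with tree cutting; each candidate is scored by the posterior expected
loss `e_K = Σ_{i<j} |I_K(i,j) − p_ij|` and the argmin is returned, ties
toward smaller `K`.

## Synthetic benchmark

The generator emulates clustered microarray data through a hierarchical
log-normal model: five clusters, sizes `2 × Poisson(λ=10)` (re-drawn
below 2), so ~100 genes; for each cluster the `N` samples split into four
constant-expression periods, sizes uniform over compositions with each
part ≥ 3 (relaxed to ≥ 1 when `N < 12`, since four parts above 2 are
infeasible at `N = 10`); period levels `log μ ~ N(6, 1)`, per-sample
template `log T_j ~ N(log μ_{period(j)}, 1)`, per-gene values
`log x_ij ~ N(log T_j, 1)`, plus optional `N(0, extra_sd²)` technical
noise on every log value (`extra_sd ∈ {0, 1, 2}` in the benchmark).
Prior-pair regimes: A — none; B — 20% of pairs drawn across different
true clusters (mis-specified); C — all within clusters; enforcement
probabilities `Uniform(0.5, 1)`; 50 pairs per dataset by default (the
count is not externally fixed; 50 matches the per-source cap used for
real data).

This produces within-cluster gene–gene correlation ≈ 0.66 at
`extra_sd = 0` (≈ 0.47 at 1, ≈ 0.26 at 2) and between-cluster ≈ 0. What
it does not emulate: scattered/noise genes outside every cluster,
platform or batch effects, heavy-tailed noise, and correlation *between*
clusters — so passing benchmarks show correct inference under clean
block structure, not robustness to real microarray artefacts.

### Behaviour of the model on this benchmark

Two regimes of this exact model are worth knowing about, both verified
against independent numerical integration of the likelihood and by
enumerated-posterior checks:

* At `N` large relative to cluster size (e.g. `N = 100`, clusters of
  ~20), the marginal likelihood *prefers splitting* an equicorrelated
  group at correlation ≈ 0.66 (merging two halves of a 20-gene group
  costs ~55 log units), so the posterior mode is a refinement of the
  planted clustering with `K ≈ 10–13` rather than 5; a 50-pair prior
  (~70 log units) cannot reverse a ~550-unit likelihood preference.
* At `N` small relative to `n` (e.g. `N = 10`, `n ≈ 100`), the baseline
  prior `1/(n·N(n,K))` concentrates enormous mass on the single `K = 1`
  partition relative to any specific multi-cluster partition, and the
  prior-dominated likelihood agrees, so the posterior collapses to one
  cluster.

Consequently the package's cluster-number-recovery and
priors-help-at-small-N benchmark tests fail under these study
conditions; they are kept as written, and the failures are a property of
the model at these noise levels and dimensions, not of the sampler
(which is exact on enumerable instances).

## Real-data plumbing

Raw prior scores map to probabilities by sigmoid transforms: iRefIndex
`lpr` (low = reliable) via `sigmoid(1/lpr)` with `lpr = 0 → 0.5`
(the stated transform is undefined at 0; 0.5 is the published value);
TF-binding scores via `sigmoid(score)`; percent sequence identity via
`sigmoid(0.1·(identity − 50))` (a raw sigmoid saturates on a 0–100
scale; centre and scale are configurable module constants). Per source
the top 50 pairs by probability are kept; duplicates across sources keep
the maximum; pairs naming genes outside the expression matrix are
dropped with a warning (prior databases are genome-wide); cycle removal
runs last. Differential-expression preselection uses Welch's t-test
(pooled variance available via a flag), Benjamini–Hochberg FDR at 5%,
then the top 400 genes by absolute log-fold-change.

## Defaults and problem sizes

Production sampler defaults: 150 000 iterations, 50 000 burn-in, keep
every 100th sample, 4 temperatures at ratio 0.7, 200 Monte-Carlo prior
draws. The test suite uses scaled-down runs chosen to keep each check
sharp at small cost: 2×10⁵ iterations for the n = 5 exactness check,
2×10⁴-iteration chains and 5–10 replicates for the benchmark twins.

## Known limitations

* Exact prior evaluation is exponential in the number of *co-grouped*
  prior pairs; the Monte-Carlo path makes the acceptance ratio noisy
  (the chain then targets a slightly smoothed posterior).
* No negative ("must-not-link") priors, no priors on triples.
* The baseline prior's uniform-over-K structure makes `P_b` depend on
  `n` and favours extreme `K` when the data are weak (see above); a
  fixed-`P_b` or hierarchical baseline would behave differently but
  would no longer be this model.
* Non-normal likelihoods and missing data are out of scope.
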