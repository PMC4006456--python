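# mcip — MCMC Clustering with Informative Priors

Bayesian model-based clustering of gene-expression profiles in which
pairwise prior knowledge — protein–protein interactions,
transcription-factor binding predictions, protein sequence similarity —
shapes the prior over partitions. Intended for analysts who have a
differentially-expressed gene list plus interaction-database evidence and
want co-regulated functional modules rather than purely data-driven
clusters.

## The model in brief

For `n` genes measured over `N` samples, a grouping
`g = (g_1, …, g_n)` assigns each gene to one of `K` groups. The
posterior is `P(g | D, M) ∝ P(D | g) P(g | M)`:

* **Likelihood.** Standardised expression within a group is zero-mean
  multivariate normal with an inverse-Wishart covariance prior
  (`Ψ_k = I`, `m_k = n_k + 2`); the covariance integrates out to a
  closed-form marginal with multivariate-gamma and log-determinant
  terms. Groups are independent.
* **Prior.** Each prior pair `(i_m, j_m, p_m)` is *enforced* (forced
  co-grouped) with probability `p_m`; summing over enforcement masks
  gives a mixture whose components apply the uniform-over-K baseline
  measure `1/((n−x) N(n−x, K))` to the `n−x` merged units, with
  `N(n, K)` the partition-count recursion
  `N(n,K) = K·N(n−1,K) + N(n−1,K−1)`. Cyclic prior sets are reduced to a
  maximum-weight spanning forest first.
* **Inference.** Metropolis–Hastings over partitions with split/merge/
  move proposals and optional parallel tempering; samples are condensed
  into a posterior similarity matrix and the reported clustering
  minimises the posterior expected loss `e_K = Σ_{i<j} |I_K(i,j) − p_ij|`.

See `docs/methods.md` for the full account, including where this model
prefers coarser or finer partitions than a planted truth.

## Worked example

```python
import numpy as np
from mcip import MCIPClustering, baseline_pair_probability

rng = np.random.default_rng(0)
base = rng.normal(size=(3, 40))                      # three expression programs
X = np.repeat(base, [4, 4, 4], axis=0)               # 12 genes x 40 samples
X += 0.25 * rng.normal(size=X.shape)

model = MCIPClustering(n_iterations=10_000, burn_in=2_000, thin=10,
                       n_temperatures=2, random_state=1)
model.fit(X, prior_pairs=[("0", "1", 0.9)])
print("inferred clusters:", model.n_clusters_)
print("labels:", model.labels_)
print("co-clustering of the prior pair:", model.posterior_similarity_[0, 1])
print("baseline co-grouping probability at n=12:",
      round(baseline_pair_probability(12), 3))
```

prints

```
inferred clusters: 3
labels: [1 1 1 1 2 2 2 2 3 3 3 3]
co-clustering of the prior pair: 1.0
baseline co-grouping probability at n=12: 0.221
```

The estimator recovered the three planted four-gene programs
(`n_clusters_` minimises the posterior expected loss over the K-sweep),
genes 0 and 1 — linked by a 0.9 must-link prior and by their shared
program — co-clustered in every retained MCMC sample, and 0.221 is the
chance that two arbitrary genes share a group under the uninformative
baseline prior at this problem size.

The same pipeline is scriptable from the shell:

```sh
mcip simulate --out-dir sim --scenario C --n-samples 100 --seed 1
mcip cluster  --expression sim/expression.tsv --priors sim/priors.tsv \
              --out-dir run --seed 1
mcip evaluate --clusters run/clusters.tsv --truth sim/truth.tsv
mcip select-genes --expression expr.tsv --labels labels.tsv --out genes.txt
```

All files are tab-separated text; `cluster` writes the cluster table,
posterior similarity matrix, sampler trace, prior audit and a run
manifest.

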