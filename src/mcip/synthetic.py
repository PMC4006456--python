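"""Synthetic clustered expression data and prior-pair scenarios.

The benchmark generator emulates microarray-style data with a known
cluster structure, via a hierarchical log-normal model.  For each of
``n_clusters`` clusters (default five, sizes ``2 x Poisson(lambda)`` with
``lambda = 10``, so about 100 genes in total):

1. the ``N`` samples are divided into four periods of constant expression,
   and each period gets a cluster template level ``log mu ~ N(mu, sigma^2)``;
2. sample variability: ``log T_j ~ N(log mu_{period(j)}, sigma_s^2)``;
3. gene variability: ``log x_ij ~ N(log T_j, sigma_0^2)`` for every gene
   ``i`` of the cluster.

Finally, independent ``N(0, extra_sd^2)`` noise is added to every
log-expression value to mimic technical error (``extra_sd`` 0, 1 or 2 in
the benchmark).  Values are returned on the log scale, un-standardised.

Prior pairs for the three benchmark regimes are drawn from the true
labels: scenario A uses no priors (q = 0), scenario B draws 20% of the
pairs across different true clusters (mis-specified), scenario C draws all
pairs within clusters; enforcement probabilities are Uniform(0.5, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .likelihood import ExpressionMatrix
from .partitions import Grouping
from .prior_model import PriorPair, PriorSet, remove_cycles

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_expression",
    "generate_prior_pairs",
    "simulate_dataset",
    "SCENARIO_MISSPEC",
]

# benchmark prior regimes: fraction of mis-specified pairs (None = no priors)
SCENARIO_MISSPEC: dict[str, float | None] = {"A": None, "B": 0.2, "C": 0.0}


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the benchmark's study conditions."""

    n_clusters: int = 5
    lam: float = 10.0  # half the expected cluster size
    n_samples: int = 100
    mu: float = 6.0
    sigma: float = 1.0
    sigma_s: float = 1.0
    sigma_0: float = 1.0
    extra_sd: float = 0.0
    n_periods: int = 4
    n_prior_pairs: int = 50
    seed: int | None = None

    def __post_init__(self):
        for name in ("sigma", "sigma_s", "sigma_0", "extra_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_clusters < 1 or self.n_periods < 1:
            raise ValueError("n_clusters and n_periods must be >= 1")
        if self.n_samples < self.n_periods:
            raise ValueError(
                f"need at least {self.n_periods} samples for {self.n_periods} periods"
            )


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix  # log scale, NOT standardised
    true_labels: Grouping
    prior_pairs: PriorSet = field(default_factory=lambda: PriorSet([], []))
    pair_truth: list[bool] = field(default_factory=list)  # per kept pair


def _period_sizes(N: int, n_periods: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform composition of N into n_periods parts, each >= 3 when feasible.

    For very small N (fewer than 3 per period) the floor relaxes to 1.
    """
    floor = 3 if N >= 3 * n_periods else 1
    free = N - floor * n_periods
    # stars and bars: uniform composition of `free` into n_periods parts >= 0
    cuts = np.sort(rng.choice(free + n_periods - 1, size=n_periods - 1, replace=False))
    parts = np.diff(np.concatenate([[-1], cuts, [free + n_periods - 1]])) - 1
    return parts + floor


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SyntheticDataset:
    """Generate log-scale clustered expression data (no prior pairs yet)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = []
    for _ in range(config.n_clusters):
        while True:
            n_c = 2 * int(rng.poisson(config.lam))
            if n_c >= 2:
                break
        sizes.append(n_c)
    N = config.n_samples
    blocks = []
    labels = []
    for c, n_c in enumerate(sizes, start=1):
        m = _period_sizes(N, config.n_periods, rng)
        period_of_sample = np.repeat(np.arange(config.n_periods), m)
        log_mu = rng.normal(config.mu, config.sigma, size=config.n_periods)
        log_T = rng.normal(log_mu[period_of_sample], config.sigma_s)  # per sample
        log_x = rng.normal(log_T[:, None], config.sigma_0, size=(N, n_c))
        blocks.append(log_x)
        labels.extend([c] * n_c)
    values = np.concatenate(blocks, axis=1)
    if config.extra_sd > 0:
        values = values + rng.normal(0.0, config.extra_sd, size=values.shape)
    n_genes = values.shape[1]
    expr = ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i + 1}" for i in range(n_genes)],
        sample_ids=[f"s{j + 1}" for j in range(N)],
        standardized=False,
    )
    return SyntheticDataset(expression=expr, true_labels=Grouping(labels))


def generate_prior_pairs(
    true_labels: Grouping,
    gene_ids: list[str],
    q: int,
    misspec_fraction: float,
    rng: np.random.Generator,
) -> tuple[PriorSet, list[bool]]:
    """Draw q prior pairs from the true clustering, a fraction mis-specified.

    ``round(q * (1 - f))`` pairs link genes of the same true cluster
    (correct) and ``round(q * f)`` link genes of different clusters
    (mis-specified); enforcement probabilities are Uniform(0.5, 1).  The
    result is reduced to a forest by cycle removal; the returned truth
    flags align with the kept pairs.
    """
    if not 0.0 <= misspec_fraction <= 1.0:
        raise ValueError("misspec_fraction must be in [0, 1]")
    labels = true_labels.labels
    within = [
        (i, j) for i, j in combinations(range(true_labels.n), 2)
        if labels[i] == labels[j]
    ]
    between = [
        (i, j) for i, j in combinations(range(true_labels.n), 2)
        if labels[i] != labels[j]
    ]
    n_bad = round(q * misspec_fraction)
    n_good = q - n_bad
    if n_good > len(within) or n_bad > len(between):
        raise ValueError(
            f"requested {n_good} within-cluster and {n_bad} between-cluster "
            f"pairs but only {len(within)}/{len(between)} exist"
        )
    chosen_within = [within[t] for t in rng.choice(len(within), n_good, replace=False)]
    chosen_between = [between[t] for t in rng.choice(len(between), n_bad, replace=False)]
    pairs = []
    flags = {}
    for (i, j), correct in [(p, True) for p in chosen_within] + [
        (p, False) for p in chosen_between
    ]:
        p_val = rng.uniform(0.5, 1.0)
        pair = PriorPair(gene_ids[i], gene_ids[j], p_val)
        pairs.append(pair)
        flags[pair.key] = correct
    prior_set, _removed = remove_cycles(pairs, gene_universe=gene_ids)
    truth = [flags[p.key] for p in prior_set.pairs]
    return prior_set, truth


def simulate_dataset(
    config: SimulationConfig,
    scenario: str = "A",
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Expression plus the prior pairs of benchmark scenario A, B or C."""
    if scenario not in SCENARIO_MISSPEC:
        raise ValueError(f"scenario must be one of {sorted(SCENARIO_MISSPEC)}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ds = simulate_expression(config, rng)
    f = SCENARIO_MISSPEC[scenario]
    if f is None:
        ds.prior_pairs = PriorSet([], list(ds.expression.gene_ids))
        ds.pair_truth = []
    else:
        ds.prior_pairs, ds.pair_truth = generate_prior_pairs(
            ds.true_labels, ds.expression.gene_ids, config.n_prior_pairs, f, rng
        )
    return ds
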