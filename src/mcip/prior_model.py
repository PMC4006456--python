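"""Informative prior over groupings driven by pairwise "must-link" knowledge.

Prior knowledge arrives as gene pairs ``(i, j, p)`` where ``p`` is the
probability of *forcing* the two genes into the same group.  The prior over
partitions is a mixture over enforcement masks ``X`` (one bit per pair):
with probability ``prod p_m^X_m (1-p_m)^(1-X_m)`` the pairs with ``X_m = 1``
are forced together, merging the ``n`` genes into ``n - x`` units, and the
baseline (uniform-over-K) measure is applied to partitions of those units:

    P(g | M) = sum_X prod_m p_m^X_m (1-p_m)^(1-X_m)
               * I(K_g <= n-x, every forced pair co-grouped in g)
               / ((n-x) * N(n-x, K_g)).

The ``n - x`` accounting is only valid when the enforced edges never form a
cycle, hence the pair set is reduced to a maximum-weight spanning forest
first (within a cycle, the weakest pair is interpreted as implied by the
others and dropped).

Pairs with ``p = 1`` are clamped just below 1 so the factored exact sum
never hits log(0) mixture weights; a truly hard constraint is better
expressed by pre-merging the genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .partitions import Grouping, log_baseline_prior, log_partition_count

__all__ = [
    "PriorPair",
    "PriorSet",
    "remove_cycles",
    "pair_force_probability",
    "total_pair_prior_probability",
    "log_prior_exact",
    "log_prior_mc",
]

ENUMERATION_GUARD = 20
_P_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class PriorPair:
    """One unordered prior pair with enforcement probability ``p``."""

    gene_i: str
    gene_j: str
    p: float
    source: str = ""

    def __post_init__(self):
        if self.gene_i == self.gene_j:
            raise ValueError(f"self-pair {self.gene_i!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if self.p == 1.0:
            object.__setattr__(self, "p", _P_CLAMP)

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_i, self.gene_j))


@dataclass
class PriorSet:
    """Acyclic collection of prior pairs over a gene universe."""

    pairs: list[PriorPair] = field(default_factory=list)
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self):
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate unordered pairs in PriorSet")
        universe = set(self.gene_universe)
        if universe:
            stray = {g for p in self.pairs for g in (p.gene_i, p.gene_j)} - universe
            if stray:
                raise ValueError(f"pairs reference genes outside universe: {sorted(stray)}")
        if _has_cycle(self.pairs):
            raise ValueError("prior pairs contain a cycle; apply remove_cycles first")

    @property
    def q(self) -> int:
        return len(self.pairs)

    def indexed(self, gene_index: dict[str, int]) -> list[tuple[int, int, float]]:
        """Pairs as (i, j, p) integer triples for a gene-id -> column map."""
        return [(gene_index[p.gene_i], gene_index[p.gene_j], p.p) for p in self.pairs]


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _has_cycle(pairs: Sequence[PriorPair]) -> bool:
    uf = _UnionFind({g for p in pairs for g in (p.gene_i, p.gene_j)})
    return any(not uf.union(p.gene_i, p.gene_j) for p in pairs)


def remove_cycles(
    pairs: Sequence[PriorPair], gene_universe: Sequence[str] | None = None
) -> tuple[PriorSet, list[PriorPair]]:
    """Reduce prior pairs to a maximum-weight spanning forest by ``p``.

    Within every cycle the pair with the smallest enforcement probability is
    interpreted as implied by the rest of the cycle and removed.  This is
    Kruskal's algorithm on edges sorted by decreasing ``p`` (equal ``p``
    broken by input order, so output is deterministic).  Returns the forest
    and the list of removed pairs.
    """
    keys = [p.key for p in pairs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate unordered pairs; merge duplicates (max p) first")
    order = sorted(range(len(pairs)), key=lambda m: (-pairs[m].p, m))
    uf = _UnionFind({g for p in pairs for g in (p.gene_i, p.gene_j)})
    kept_idx = [m for m in order if uf.union(pairs[m].gene_i, pairs[m].gene_j)]
    kept_set = set(kept_idx)
    kept = [pairs[m] for m in range(len(pairs)) if m in kept_set]
    removed = [pairs[m] for m in range(len(pairs)) if m not in kept_set]
    universe = list(gene_universe) if gene_universe is not None else sorted(
        {g for p in pairs for g in (p.gene_i, p.gene_j)}
    )
    return PriorSet(pairs=kept, gene_universe=universe), removed


def pair_force_probability(pairs: Sequence[PriorPair], a: str, b: str) -> float:
    """Probability that genes ``a`` and ``b`` are *forced* together.

    Sums, over all 2^q enforcement masks, the mask probability times the
    indicator that the enforced edges connect ``a`` and ``b``.  The baseline
    measure is disregarded; this is the quantity that motivates cycle
    removal (in an all-0.8 triangle it is 0.928, not 0.8).
    """
    q = len(pairs)
    if q > ENUMERATION_GUARD:
        raise ValueError(f"q={q} exceeds enumeration guard {ENUMERATION_GUARD}")
    total = 0.0
    for mask in range(1 << q):
        w = 1.0
        uf = _UnionFind({g for p in pairs for g in (p.gene_i, p.gene_j)} | {a, b})
        for m in range(q):
            if mask >> m & 1:
                w *= pairs[m].p
                uf.union(pairs[m].gene_i, pairs[m].gene_j)
            else:
                w *= 1.0 - pairs[m].p
        if uf.find(a) == uf.find(b):
            total += w
    return total


def total_pair_prior_probability(p: float, P_b: float) -> float:
    """Total prior probability that a prior pair is co-grouped.

    Even an unenforced pair can land in the same group under the baseline
    measure, so the total is the mixture ``p + (1 - p) * P_b``.
    """
    if not (0.0 <= p <= 1.0) or not (0.0 <= P_b <= 1.0):
        raise ValueError(f"p and P_b must be in [0, 1], got {p}, {P_b}")
    return p + (1.0 - p) * P_b


def _split_pairs(g: Grouping, M: PriorSet, gene_index: dict[str, int] | None):
    """Partition M's pairs into those co-grouped in g and those split by g."""
    if gene_index is None:
        gene_index = {gid: i for i, gid in enumerate(M.gene_universe)}
    co, split = [], []
    for pair in M.pairs:
        i, j = gene_index[pair.gene_i], gene_index[pair.gene_j]
        (co if g.labels[i] == g.labels[j] else split).append(pair.p)
    return co, split


def log_prior_exact(
    g: Grouping, M: PriorSet, gene_index: dict[str, int] | None = None
) -> float:
    """Exact log P(g | M) by enumeration over enforcement masks.

    Factored: a pair split by ``g`` can never be enforced, so it contributes
    the deterministic weight ``(1 - p_m)``; enumeration runs only over the
    pairs co-grouped in ``g``.
    """
    co, split = _split_pairs(g, M, gene_index)
    if len(co) > ENUMERATION_GUARD:
        raise ValueError(
            f"{len(co)} co-grouped prior pairs exceed the enumeration guard "
            f"({ENUMERATION_GUARD}); use log_prior_mc"
        )
    log_fixed = float(np.sum(np.log1p(-np.asarray(split)))) if split else 0.0
    n, K = g.n, g.K
    s = len(co)
    with np.errstate(divide="ignore"):
        log_p = np.log(np.asarray(co)) if co else np.empty(0)
    log_1mp = np.log1p(-np.asarray(co)) if co else np.empty(0)
    total = -math.inf
    for mask in range(1 << s):
        x = mask.bit_count()
        if K > n - x:
            continue
        lw = 0.0
        for m in range(s):
            lw += log_p[m] if mask >> m & 1 else log_1mp[m]
        term = lw - math.log(n - x) - log_partition_count(n - x, K)
        total = np.logaddexp(total, term)
    return log_fixed + float(total)


def log_prior_mc(
    g: Grouping,
    M: PriorSet,
    n_samples: int = 200,
    rng: np.random.Generator | None = None,
    gene_index: dict[str, int] | None = None,
) -> float:
    """Monte-Carlo estimate of log P(g | M) for many prior pairs.

    Importance sampling with the Bernoulli mask prior as proposal, after
    factoring out the pairs split by ``g`` (which contribute exactly
    ``prod (1 - p_m)``): draw masks over the co-grouped pairs from
    ``X_m ~ Bernoulli(p_m)`` and average ``I(K_g <= n-x) / ((n-x) N(n-x, K_g))``.
    Zero variance when no prior pair is co-grouped (the estimate is exact).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    co, split = _split_pairs(g, M, gene_index)
    log_fixed = float(np.sum(np.log1p(-np.asarray(split)))) if split else 0.0
    n, K = g.n, g.K
    if not co:
        return log_fixed - math.log(n) - log_partition_count(n, K)
    p = np.asarray(co)
    draws = rng.random((n_samples, p.size)) < p  # Bernoulli(p_m) masks
    x = draws.sum(axis=1)
    # log of 1 / ((n-x) N(n-x, K)), -inf where K > n-x
    vals = np.full(n_samples, -np.inf)
    for xv in np.unique(x):
        units = n - int(xv)
        if K <= units:
            vals[x == xv] = -math.log(units) - log_partition_count(units, K)
    m = vals.max()
    if m == -np.inf:
        return -math.inf
    mean = np.exp(vals - m).mean()
    return log_fixed + float(m + np.log(mean))
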