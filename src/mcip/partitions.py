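"""Exact combinatorics of set partitions, in log space.

The number of ways to partition ``n`` genes into exactly ``K`` non-empty
groups is the Stirling number of the second kind, written ``N(n, K)``
throughout this package.  It satisfies

    N(n, K) = K * N(n-1, K) + N(n-1, K-1),        N(K, K) = 1,

because a new gene either joins one of the ``K`` existing groups or starts
its own.  ``N(100, K)`` has well over 100 digits, so every count is kept as
a log; an exact big-integer cross-check for small ``n`` lives in the test
suite.

The module also provides the *baseline prior* over groupings -- uniform on
the number of groups ``K`` and uniform over groupings given ``K`` -- and the
baseline probability ``P_b`` that two arbitrary genes are co-grouped under
that prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Grouping",
    "PartitionCountTable",
    "log_partition_count",
    "log_total_partitions",
    "baseline_pair_probability",
    "log_baseline_prior",
    "sample_baseline_grouping",
]

_NEG_INF = float("-inf")


@dataclass
class PartitionCountTable:
    """Memoised table of ``log N(n, K)`` for ``1 <= K <= n <= max_n``.

    Grown lazily: asking for a larger ``n`` extends the table in place.
    ``log_counts[n]`` is a float array of length ``n + 1`` whose entry ``K``
    holds ``log N(n, K)`` (entry 0 is -inf padding).
    """

    max_n: int = 0
    log_counts: list[np.ndarray] = field(default_factory=list)

    def _extend(self, n: int) -> None:
        if not self.log_counts:
            # rows 0 and 1: N(1, 1) = 1
            self.log_counts.append(np.array([_NEG_INF]))
            self.log_counts.append(np.array([_NEG_INF, 0.0]))
            self.max_n = 1
        while self.max_n < n:
            m = self.max_n + 1
            prev = self.log_counts[m - 1]
            row = np.full(m + 1, _NEG_INF)
            K = np.arange(1, m + 1)
            # left term K*N(m-1,K): undefined for K = m (prev has no entry m)
            left = np.full(m, _NEG_INF)
            left[: m - 1] = np.log(K[: m - 1]) + prev[1:m]
            # right term N(m-1, K-1); N(m-1, 0) = 0
            right = np.full(m, _NEG_INF)
            right[1:] = prev[1:m]
            row[1:] = np.logaddexp(left, right)
            row[m] = 0.0  # N(m, m) = 1 exactly
            row[1] = 0.0  # N(m, 1) = 1 exactly
            self.log_counts.append(row)
            self.max_n = m

    def log_count(self, n: int, K: int) -> float:
        if n < 1 or K < 1:
            raise ValueError(f"n and K must be positive, got n={n}, K={K}")
        if K > n:
            return _NEG_INF
        self._extend(n)
        return float(self.log_counts[n][K])

    def row(self, n: int) -> np.ndarray:
        """Array of log N(n, K) for K = 1..n (index 0 is -inf padding)."""
        self._extend(n)
        return self.log_counts[n]


_TABLE = PartitionCountTable()


def log_partition_count(n: int, K: int) -> float:
    """log of the number of partitions of ``n`` items into exactly ``K`` groups.

    Returns ``-inf`` when ``K > n`` (no such partition exists).
    """
    return _TABLE.log_count(n, K)


def log_total_partitions(n: int) -> float:
    """log of the total number of partitions of ``n`` items (Bell number)."""
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    row = _TABLE.row(n)
    return float(logsumexp_row(row[1:]))


def logsumexp_row(values: np.ndarray) -> float:
    m = np.max(values)
    if m == _NEG_INF:
        return _NEG_INF
    return float(m + np.log(np.sum(np.exp(values - m))))


def baseline_pair_probability(n: int) -> float:
    """Baseline probability P_b that two arbitrary genes share a group.

    Under the baseline prior (uniform over K, uniform over groupings given
    K) the chance that two given genes are co-grouped is

        P_b = (1/n) * sum_K N(n-1, K) / N(n, K),

    which decreases with the total number of genes ``n``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    prev = _TABLE.row(n - 1)
    curr = _TABLE.row(n)
    # N(n-1, K) / N(n, K) for K = 1..n; the K = n term is exp(-inf) = 0
    log_ratio = np.concatenate([prev[1:], [_NEG_INF]]) - curr[1:]
    return float(np.sum(np.exp(log_ratio)) / n)


class Grouping:
    """A partition of ``n`` genes into ``K`` labeled groups.

    Labels are canonicalised by order of first appearance (gene 0 is always
    in group 1, the first gene not grouped with it opens group 2, and so
    on), since labels are exchangeable in every probability formula.
    """

    __slots__ = ("labels", "n", "K")

    def __init__(self, labels: Sequence[int]):
        labels = np.asarray(labels, dtype=np.int64)
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        self.labels = _canonicalise(labels)
        self.n = int(labels.size)
        self.K = int(self.labels.max())

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[int]], n: int) -> "Grouping":
        labels = np.full(n, -1, dtype=np.int64)
        for k, members in enumerate(groups, start=1):
            for i in members:
                labels[i] = k
        if (labels < 0).any():
            missing = np.flatnonzero(labels < 0).tolist()
            raise ValueError(f"genes {missing} not assigned to any group")
        return cls(labels)

    def groups(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.K)]
        for i, lab in enumerate(self.labels):
            out[lab - 1].append(i)
        return out

    def co_grouped(self, i: int, j: int) -> bool:
        return self.labels[i] == self.labels[j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grouping):
            return NotImplemented
        return self.n == other.n and bool(np.array_equal(self.labels, other.labels))

    def __hash__(self) -> int:
        return hash(self.labels.tobytes())

    def __repr__(self) -> str:  # pragma: no cover
        return f"Grouping(n={self.n}, K={self.K}, labels={self.labels.tolist()})"


def _canonicalise(labels: np.ndarray) -> np.ndarray:
    relabel: dict[int, int] = {}
    out = np.empty_like(labels)
    nxt = 1
    for idx, lab in enumerate(labels):
        key = int(lab)
        if key not in relabel:
            relabel[key] = nxt
            nxt += 1
        out[idx] = relabel[key]
    return out


def log_baseline_prior(g: Grouping) -> float:
    """log P(g | M_0) = -log n - log N(n, K_g) under the baseline prior."""
    return -np.log(g.n) - log_partition_count(g.n, g.K)


def sample_baseline_grouping(n: int, rng: np.random.Generator) -> Grouping:
    """Draw a grouping from the baseline prior.

    K is uniform on 1..n; given K the grouping is uniform among the
    N(n, K) possibilities, sampled by sequential placement: working from the
    last gene down, gene m starts its own group with probability
    N(m-1, K-1) / N(m, K) and otherwise joins one of the K groups that the
    first m-1 genes will occupy (chosen uniformly once those are placed).
    """
    if n < 1:
        raise ValueError("n must be positive")
    K = int(rng.integers(1, n + 1))
    labels = np.zeros(n, dtype=np.int64)
    # backward pass: decide for gene m (last to first) whether it opens a
    # fresh block -- N(m-1, k-1) of the N(m, k) partitions -- or joins one
    # of the k blocks of the first m-1 genes (k * N(m-1, k) partitions)
    opens = np.zeros(n, dtype=bool)
    k_rem = K
    for m in range(n, 0, -1):
        if m == k_rem:
            opens[:m] = True  # all-singletons forced
            break
        if k_rem == 1:
            opens[m - 1] = False  # a single block: everyone joins gene 1's
            continue
        log_open = log_partition_count(m - 1, k_rem - 1)
        log_join = np.log(k_rem) + log_partition_count(m - 1, k_rem)
        if np.log(rng.random()) < log_open - np.logaddexp(log_open, log_join):
            opens[m - 1] = True
            k_rem -= 1
    opens[0] = True  # gene 1 always opens the first block
    # forward pass: joiners choose uniformly among blocks already opened
    open_labels: list[int] = []
    next_label = 1
    for i in range(n):
        if opens[i]:
            labels[i] = next_label
            open_labels.append(next_label)
            next_label += 1
        else:
            labels[i] = open_labels[int(rng.integers(0, len(open_labels)))]
    return Grouping(labels)


def enumerate_partitions(n: int) -> list[Grouping]:
    """All partitions of ``n`` items (for small n; test and exact-posterior use)."""
    if n < 1:
        raise ValueError("n must be positive")
    results: list[Grouping] = []

    def rec(i: int, labels: list[int], k: int) -> None:
        if i == n:
            results.append(Grouping(labels))
            return
        for lab in range(1, k + 2):
            rec(i + 1, labels + [lab], max(k, lab))

    rec(0, [], 0)
    return results
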