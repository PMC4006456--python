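"""Posterior summaries: similarity matrix and minimum-loss clustering.

The MCMC samples are condensed into the posterior similarity matrix (PSM),
whose entry ``(i, j)`` is the proportion of samples in which genes ``i``
and ``j`` share a group.  Candidate clusterings for ``K = 1..L`` come from
average-linkage hierarchical clustering on the dissimilarity ``1 - p`` with
tree cutting; each candidate is scored by the posterior expected loss under
absolute-difference loss,

    e_K = sum_{i<j} | I_K(i, j) - p_ij |,

and the candidate minimising ``e_K`` is returned (ties broken toward the
smaller, more parsimonious K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .partitions import Grouping

__all__ = [
    "PosteriorSimilarityMatrix",
    "ClusteringResult",
    "posterior_similarity",
    "posterior_expected_loss",
    "infer_clusters",
]


@dataclass
class PosteriorSimilarityMatrix:
    """n x n co-clustering proportions from MCMC samples."""

    p: np.ndarray
    n_samples_used: int

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("PSM must be square")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("PSM must be symmetric")
        if (self.p < 0).any() or (self.p > 1).any():
            raise ValueError("PSM entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.p.shape[0]


@dataclass
class ClusteringResult:
    grouping: Grouping
    K_hat: int
    loss_curve: np.ndarray  # e_K for K = 1..L


def posterior_similarity(samples: Sequence[Grouping]) -> PosteriorSimilarityMatrix:
    """Pairwise co-clustering proportions over the given samples."""
    if len(samples) == 0:
        raise ValueError("need at least one MCMC sample")
    n = samples[0].n
    acc = np.zeros((n, n))
    for g in samples:
        if g.n != n:
            raise ValueError("samples are over different gene sets")
        acc += g.labels[:, None] == g.labels[None, :]
    p = acc / len(samples)
    np.fill_diagonal(p, 1.0)
    return PosteriorSimilarityMatrix(p=p, n_samples_used=len(samples))


def posterior_expected_loss(
    psm: PosteriorSimilarityMatrix, partition: Grouping
) -> float:
    """e_K = sum over unordered pairs of |co-grouping indicator - p_ij|."""
    if partition.n != psm.n:
        raise ValueError("partition and PSM dimensions differ")
    ind = partition.labels[:, None] == partition.labels[None, :]
    iu = np.triu_indices(psm.n, k=1)
    return float(np.abs(ind[iu].astype(float) - psm.p[iu]).sum())


def infer_clusters(
    psm: PosteriorSimilarityMatrix, L: int = 30, method: str = "average"
) -> ClusteringResult:
    """Minimum-posterior-expected-loss clustering from the PSM.

    ``method`` is the agglomerative linkage ("average" or "complete")
    applied to the dissimilarity ``1 - p``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    L = min(L, psm.n)
    if method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    dist = 1.0 - psm.p
    np.fill_diagonal(dist, 0.0)
    if psm.n == 1:
        g = Grouping([1])
        return ClusteringResult(g, 1, np.zeros(1))
    Z = linkage(squareform(dist, checks=False), method=method)
    losses = np.empty(L)
    candidates: list[Grouping] = []
    for K in range(1, L + 1):
        labels = fcluster(Z, t=K, criterion="maxclust")
        g = Grouping(labels)
        candidates.append(g)
        losses[K - 1] = posterior_expected_loss(psm, g)
    K_hat = int(np.argmin(losses)) + 1  # argmin takes the first (smallest K) tie
    return ClusteringResult(candidates[K_hat - 1], candidates[K_hat - 1].K, losses)
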