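"""Scoring of inferred partitions.

Two complementary views: agreement with a known true partition (adjusted
Rand index) and agreement with an external reference *pair network*
(sensitivity / specificity / positive predictive value over all unordered
gene pairs, with a single-operating-point AUC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .partitions import Grouping
from .summarize import PosteriorSimilarityMatrix

__all__ = [
    "PairConfusion",
    "adjusted_rand",
    "pair_confusion",
    "auc_single_point",
    "psm_roc_auc",
]


@dataclass
class PairConfusion:
    """Confusion counts over all n(n-1)/2 unordered gene pairs.

    A pair is "positive" when the inferred partition co-groups it; "true"
    when it appears in the reference network.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP) if self.TN + self.FP else float("nan")

    @property
    def ppv(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else float("nan")


def adjusted_rand(a: Grouping, b: Grouping) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 for identical partitions, expected 0 for random labelings.
    """
    if a.n != b.n:
        raise ValueError(f"partitions over different gene sets ({a.n} vs {b.n})")
    return float(adjusted_rand_score(a.labels, b.labels))


def pair_confusion(
    partition: Grouping,
    reference_pairs: Sequence[tuple[int, int]],
) -> PairConfusion:
    """Confusion table of co-grouped pairs against a reference pair list.

    ``reference_pairs`` holds unordered gene-index pairs (deduplicated);
    indices outside the partition's gene range are an error.
    """
    n = partition.n
    ref = set()
    bad = []
    for i, j in reference_pairs:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            bad.append((i, j))
        else:
            ref.add(frozenset((i, j)))
    if bad:
        raise ValueError(f"reference pairs outside gene universe: {bad}")
    labels = partition.labels
    TP = FP = TN = FN = 0
    for i in range(n):
        for j in range(i + 1, n):
            pos = labels[i] == labels[j]
            true = frozenset((i, j)) in ref
            if pos and true:
                TP += 1
            elif pos:
                FP += 1
            elif true:
                FN += 1
            else:
                TN += 1
    return PairConfusion(TP, FP, TN, FN)


def auc_single_point(sensitivity: float, specificity: float) -> float:
    """Area under the ROC through (0,0), (1-spec, sens), (1,1).

    A clustering yields one operating point, so the ROC is the two-segment
    polyline through it; its trapezoidal area reduces to
    ``(sensitivity + specificity) / 2``.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return (sensitivity + specificity) / 2.0


def psm_roc_auc(
    psm: PosteriorSimilarityMatrix,
    reference_pairs: Sequence[tuple[int, int]],
) -> float:
    """Full-ROC AUC from sweeping a co-clustering threshold over the PSM.

    Richer than the single operating point of a hard clustering: every
    unordered pair is scored by its posterior co-clustering proportion
    ``p_ij`` and ranked against membership in the reference network.
    Requires the reference to contain at least one pair and to leave at
    least one pair out.
    """
    n = psm.n
    ref = {frozenset(p) for p in reference_pairs}
    bad = [tuple(p) for p in ref if not all(0 <= i < n for i in p) or len(p) != 2]
    if bad:
        raise ValueError(f"reference pairs outside gene universe: {bad}")
    iu = np.triu_indices(n, k=1)
    scores = psm.p[iu]
    truth = np.array(
        [frozenset((i, j)) in ref for i, j in zip(*iu)], dtype=bool
    )
    if truth.all() or not truth.any():
        raise ValueError("reference network must label some pairs positive "
                         "and some negative")
    return float(roc_auc_score(truth, scores))
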