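"""Readers, writers, prior-score transforms and gene preselection.

File formats are all tab-separated text:

* expression -- first column gene ids, header row of sample ids;
* priors     -- columns ``gene_a  gene_b  score  source``;
* labels     -- columns ``sample_id  condition`` (two conditions);
* outputs    -- clusters (``gene  cluster``), PSM (matrix with gene-id
  header), prior audit (pair, source, raw score, probability, kept flag).

Raw prior scores from the three supported evidence types are mapped to
enforcement probabilities with sigmoid transforms:

* ``ppi_lpr`` -- iRefIndex "lowest PMID re-use"; small lpr means
  low-throughput (reliable) evidence, so the sigmoid is applied to
  ``1/lpr`` (an lpr of 1 maps to 0.73; lpr 0 is mapped to 0.5);
* ``tf_score`` -- transcription-factor binding prediction score, sigmoid
  applied directly;
* ``seq_similarity`` -- percent protein sequence identity (0-100); a raw
  sigmoid saturates immediately on that scale, so a centred/scaled sigmoid
  ``sigmoid(scale * (identity - center))`` is used (defaults 0.1 and 50,
  i.e. 50% identity maps to 0.5);
* ``probability`` -- already a probability, passed through.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .likelihood import ExpressionMatrix
from .partitions import Grouping
from .prior_model import PriorPair, PriorSet, remove_cycles
from .summarize import PosteriorSimilarityMatrix

__all__ = [
    "RawPriorRecord",
    "read_expression",
    "write_expression",
    "read_prior_records",
    "read_sample_labels",
    "transform_score",
    "merge_prior_sources",
    "select_de_genes",
    "write_clusters",
    "write_psm",
    "read_psm",
]

logger = logging.getLogger(__name__)

SOURCES = ("ppi_lpr", "tf_score", "seq_similarity", "probability")

SEQ_SIM_SCALE = 0.1
SEQ_SIM_CENTER = 50.0


@dataclass(frozen=True)
class RawPriorRecord:
    gene_a: str
    gene_b: str
    score: float
    source: str

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown prior source {self.source!r}; expected {SOURCES}")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for pair ({self.gene_a}, {self.gene_b})")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV into an ExpressionMatrix (samples x genes)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene id(s) in {path}: {dup}")
    values = df.to_numpy(dtype=float).T
    if np.isnan(values).any():
        raise ValueError(f"missing values in expression file {path}")
    return ExpressionMatrix(
        values=values,
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values.T, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_prior_records(path: str | Path) -> list[RawPriorRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_a", "gene_b", "score", "source"}
    if not required.issubset(df.columns):
        raise ValueError(f"prior file {path} must have columns {sorted(required)}")
    return [
        RawPriorRecord(str(r.gene_a), str(r.gene_b), float(r.score), str(r.source))
        for r in df.itertuples(index=False)
    ]


def read_sample_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise ValueError(f"labels file {path} must have two columns")
    labels = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    counts = pd.Series(list(labels.values())).value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError("need exactly two conditions with >= 2 samples each")
    return labels


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def transform_score(record: RawPriorRecord) -> float:
    """Map a raw prior score to an enforcement probability."""
    s = record.score
    if record.source == "ppi_lpr":
        if s < 0:
            raise ValueError(f"lpr score must be >= 0, got {s}")
        if s == 0:
            return 0.5
        return _sigmoid(1.0 / s)
    if record.source == "tf_score":
        return _sigmoid(s)
    if record.source == "seq_similarity":
        return _sigmoid(SEQ_SIM_SCALE * (s - SEQ_SIM_CENTER))
    # probability: passthrough
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"probability score outside [0, 1]: {s}")
    return s


def merge_prior_sources(
    records: Sequence[RawPriorRecord],
    gene_universe: Sequence[str],
    top_k_per_source: int = 50,
) -> tuple[PriorSet, pd.DataFrame]:
    """Transform, select and merge raw prior records into a forest PriorSet.

    Per source, the ``top_k_per_source`` pairs by transformed probability
    are kept (stable order on ties); the same pair seen from several
    sources keeps its highest probability; pairs naming genes absent from
    the expression matrix are dropped with a logged warning; finally cycle
    removal reduces the pair graph to a maximum-weight spanning forest.

    Returns the PriorSet plus an audit table (one row per input record:
    raw score, probability, and whether it survived each stage).
    """
    universe = set(gene_universe)
    rows = []
    by_source: dict[str, list[tuple[float, int]]] = {}
    for idx, rec in enumerate(records):
        p = transform_score(rec)
        known = rec.gene_a in universe and rec.gene_b in universe
        rows.append(
            {
                "gene_a": rec.gene_a,
                "gene_b": rec.gene_b,
                "source": rec.source,
                "score": rec.score,
                "probability": p,
                "in_universe": known,
                "kept": False,
            }
        )
        if known:
            by_source.setdefault(rec.source, []).append((p, idx))
    n_dropped = sum(1 for r in rows if not r["in_universe"])
    if n_dropped:
        logger.warning(
            "dropped %d prior pair(s) naming genes absent from the expression matrix",
            n_dropped,
        )
    # per-source top-k by probability, stable on ties
    selected: dict[frozenset, tuple[float, int]] = {}
    for recs in by_source.values():
        order = sorted(range(len(recs)), key=lambda t: (-recs[t][0], recs[t][1]))
        for t in order[:top_k_per_source]:
            p, idx = recs[t]
            key = frozenset((rows[idx]["gene_a"], rows[idx]["gene_b"]))
            if key not in selected or p > selected[key][0]:
                selected[key] = (p, idx)
    pairs = []
    for key in sorted(selected, key=lambda k: selected[k][1]):  # stable input order
        p, idx = selected[key]
        pairs.append(
            PriorPair(rows[idx]["gene_a"], rows[idx]["gene_b"], p, rows[idx]["source"])
        )
    prior_set, removed = remove_cycles(pairs, gene_universe=list(gene_universe))
    kept_keys = {pr.key for pr in prior_set.pairs}
    for key, (p, idx) in selected.items():
        rows[idx]["kept"] = key in kept_keys
    audit = pd.DataFrame(rows)
    return prior_set, audit


def select_de_genes(
    expr: ExpressionMatrix,
    labels: dict[str, str],
    fdr_cutoff: float = 0.05,
    top_n: int = 400,
    equal_var: bool = False,
) -> list[str]:
    """Differential-expression preselection for two-condition designs.

    Per-gene two-sample t-test (Welch by default) on log-scale values,
    Benjamini-Hochberg adjustment, then among genes with adjusted p below
    ``fdr_cutoff`` the ``top_n`` with largest absolute log fold change
    (difference of group means).  Returned ids keep the input gene order.
    """
    conditions = sorted(set(labels.values()))
    if len(conditions) != 2:
        raise ValueError(f"need exactly two conditions, got {conditions}")
    idx_a = [i for i, s in enumerate(expr.sample_ids) if labels.get(s) == conditions[0]]
    idx_b = [i for i, s in enumerate(expr.sample_ids) if labels.get(s) == conditions[1]]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each condition needs at least 2 samples")
    A = expr.values[idx_a, :]
    B = expr.values[idx_b, :]
    _t, pvals = stats.ttest_ind(A, B, axis=0, equal_var=equal_var)
    _rej, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    lfc = np.abs(A.mean(axis=0) - B.mean(axis=0))
    passing = np.flatnonzero(p_adj < fdr_cutoff)
    if passing.size == 0:
        return []
    top = passing[np.argsort(-lfc[passing], kind="stable")[:top_n]]
    keep = set(top.tolist())
    return [g for i, g in enumerate(expr.gene_ids) if i in keep]


def write_clusters(
    grouping: Grouping, gene_ids: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame({"gene": list(gene_ids), "cluster": grouping.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_psm(
    psm: PosteriorSimilarityMatrix, gene_ids: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(psm.p, index=list(gene_ids), columns=list(gene_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_psm(path: str | Path) -> tuple[PosteriorSimilarityMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    psm = PosteriorSimilarityMatrix(p=df.to_numpy(dtype=float), n_samples_used=0)
    return psm, [str(g) for g in df.index]
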