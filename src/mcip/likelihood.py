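"""Marginal likelihood of the expression data given a grouping.

Each group of genes is modelled as zero-mean multivariate normal across
samples, with an inverse-Wishart prior on the within-group covariance:
``Sigma_k ~ IW(Psi_k, m_k)`` with ``Psi_k = rho_k * I`` and sharpness
``m_k = n_k + 2`` (the smallest degrees of freedom for which the prior mean
exists; with ``rho_k = 1`` it equals the identity, encoding that the data
were standardised to unit variance).  Genes in different groups are
independent, so the marginal likelihood factorises over groups, with the
covariance integrated out analytically:

    log P(X_k) = (m_k/2) log|Psi_k| + log Gamma_{n_k}((m_k+N)/2)
                 - (N n_k / 2) log pi
                 - ((m_k+N)/2) log|Psi_k + X_k' X_k|
                 - log Gamma_{n_k}(m_k/2),

where ``N`` is the number of samples and ``Gamma_p`` the multivariate gamma
function.  ``Psi_k + X_k' X_k`` is positive definite even when the Gram
matrix is singular (n_k > N), so the evaluation never fails.

The model has no mean parameter, hence standardisation (per-gene mean 0,
variance 1) is enforced rather than optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import multigammaln

from .partitions import Grouping

__all__ = [
    "ExpressionMatrix",
    "GroupLikelihoodParams",
    "standardize",
    "log_multivariate_gamma",
    "log_marginal_likelihood_group",
    "log_marginal_likelihood",
    "GroupTermCache",
]

_LOG_PI = float(np.log(np.pi))


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with identifiers.

    ``values`` has one row per sample and one column per gene (the
    transpose of the usual genes-as-rows text format, which the io module
    handles).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x genes)")
        N, n = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} columns")
        if len(self.sample_ids) != N:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {N} rows")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def gene_index(self) -> dict[str, int]:
        return {gid: i for i, gid in enumerate(self.gene_ids)}


@dataclass(frozen=True)
class GroupLikelihoodParams:
    """Inverse-Wishart hyperparameters for one group of ``n_k`` genes."""

    n_k: int
    rho: float = 1.0

    @property
    def m_k(self) -> int:
        return self.n_k + 2

    def __post_init__(self):
        if self.n_k < 0:
            raise ValueError("group size must be non-negative")
        if self.rho <= 0:
            raise ValueError("prior scale rho must be positive")


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardisation to mean 0 and (sample, N-1) variance 1."""
    if expr.standardized:
        return expr
    if expr.n_samples < 2:
        raise ValueError("standardisation needs at least 2 samples")
    mean = expr.values.mean(axis=0)
    sd = expr.values.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [expr.gene_ids[i] for i in dead]
        raise ValueError(f"constant expression for gene(s) {names}; cannot standardise")
    return replace(expr, values=(expr.values - mean) / sd, standardized=True)


def log_multivariate_gamma(p: int, a: float) -> float:
    """log Gamma_p(a) = (p(p-1)/4) log pi + sum_i log Gamma(a + (1-i)/2)."""
    if p < 1:
        raise ValueError("dimension p must be >= 1")
    if a <= (p - 1) / 2:
        raise ValueError(f"a must exceed (p-1)/2 = {(p - 1) / 2}, got {a}")
    return float(multigammaln(a, p))


def log_marginal_likelihood_group(
    X_k: np.ndarray, params: GroupLikelihoodParams | None = None
) -> float:
    """Integrated log-likelihood of one group's N x n_k submatrix."""
    X_k = np.asarray(X_k, dtype=float)
    if X_k.ndim != 2:
        raise ValueError("X_k must be 2-D (samples x group genes)")
    N, n_k = X_k.shape
    if n_k == 0:
        return 0.0
    if params is None:
        params = GroupLikelihoodParams(n_k=n_k)
    elif params.n_k != n_k:
        raise ValueError(f"params built for n_k={params.n_k}, matrix has {n_k}")
    if N == 0:
        return 0.0
    m = params.m_k
    log_det_psi = n_k * np.log(params.rho)
    S = params.rho * np.eye(n_k) + X_k.T @ X_k
    sign, log_det_S = np.linalg.slogdet(S)
    if sign <= 0:  # pragma: no cover - S is PD by construction
        raise np.linalg.LinAlgError("posterior scale matrix not positive definite")
    return (
        0.5 * m * log_det_psi
        + log_multivariate_gamma(n_k, 0.5 * (m + N))
        - 0.5 * N * n_k * _LOG_PI
        - 0.5 * (m + N) * log_det_S
        - log_multivariate_gamma(n_k, 0.5 * m)
    )


class GroupTermCache:
    """Per-group likelihood terms keyed by frozen member set.

    MCMC moves touch at most two groups per step, so re-evaluating only the
    affected groups makes the chain cost independent of K.
    """

    def __init__(self, expr: ExpressionMatrix, rho: float = 1.0):
        if not expr.standardized:
            raise ValueError("expression must be standardised (see standardize())")
        self.values = expr.values
        self.rho = rho
        self._cache: dict[frozenset, float] = {}

    def group_term(self, members: frozenset) -> float:
        try:
            return self._cache[members]
        except KeyError:
            idx = sorted(members)
            val = log_marginal_likelihood_group(
                self.values[:, idx], GroupLikelihoodParams(n_k=len(idx), rho=self.rho)
            )
            self._cache[members] = val
            return val

    def total(self, g: Grouping) -> float:
        return sum(self.group_term(frozenset(members)) for members in g.groups())


def log_marginal_likelihood(
    expr: ExpressionMatrix, g: Grouping, rho: float = 1.0
) -> float:
    """Total log P(D | g): sum of the per-group integrated likelihoods."""
    if not expr.standardized:
        raise ValueError("expression must be standardised (see standardize())")
    if g.n != expr.n_genes:
        raise ValueError(f"grouping over {g.n} genes, matrix has {expr.n_genes}")
    return GroupTermCache(expr, rho=rho).total(g)
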