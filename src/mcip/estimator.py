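"""Scikit-learn-style front end for MCMC clustering with informative priors.

``MCIPClustering`` clusters the *rows* of its input matrix (genes), using
the columns (samples) as replicated observations.  It standardises each
gene, runs the tempered Metropolis-Hastings sampler over partitions with
the pairwise-prior partition prior, condenses the samples into a posterior
similarity matrix, and picks the partition minimising the posterior
expected loss.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .likelihood import ExpressionMatrix, standardize
from .prior_model import PriorPair, PriorSet, remove_cycles
from .sampler import SamplerConfig, run_tempered
from .summarize import infer_clusters, posterior_similarity

__all__ = ["MCIPClustering"]


class MCIPClustering(ClusterMixin, BaseEstimator):
    """Bayesian partition clustering with pairwise must-link priors.

    Parameters
    ----------
    n_iterations, burn_in, thin : int
        MCMC schedule; defaults (150000 / 50000 / 100) suit a production
        run of a few hundred genes.
    n_temperatures : int
        Parallel-tempering chains (1 disables tempering).
    temperature_ratio : float
        Geometric inverse-temperature ladder ratio in (0, 1].
    mc_prior_samples : int
        Monte-Carlo draws for the partition prior when the number of
        prior pairs exceeds the exact-enumeration guard.
    max_clusters : int
        Largest K swept when minimising the posterior expected loss.
    linkage : {"average", "complete"}
        Agglomerative linkage used on the posterior similarity matrix.
    random_state : int or None
        Seed for every stochastic component.

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,)
        Inferred cluster label per gene (1-based).
    n_clusters_ : int
        Selected number of clusters (minimum posterior expected loss).
    posterior_similarity_ : ndarray of shape (n_genes, n_genes)
        Co-clustering proportions across the kept MCMC samples.
    loss_curve_ : ndarray
        Posterior expected loss e_K for K = 1..max_clusters.
    samples_ : list of Grouping
        Thinned post-burn-in partition samples from the cold chain.
    trace_ : list of TraceRecord
        Sparse trace of (iteration, log-likelihood, log-prior, K, ...).

    Examples
    --------
    >>> import numpy as np
    >>> from mcip import MCIPClustering
    >>> rng = np.random.default_rng(0)
    >>> base = rng.normal(size=(2, 30))
    >>> X = np.repeat(base, 3, axis=0) + 0.1 * rng.normal(size=(6, 30))
    >>> model = MCIPClustering(n_iterations=4000, burn_in=1000, thin=10,
    ...                        n_temperatures=1, random_state=0)
    >>> model.fit(X).n_clusters_
    2
    """

    def __init__(
        self,
        n_iterations: int = 150_000,
        burn_in: int = 50_000,
        thin: int = 100,
        n_temperatures: int = 4,
        temperature_ratio: float = 0.7,
        mc_prior_samples: int = 200,
        max_clusters: int = 30,
        linkage: str = "average",
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thin = thin
        self.n_temperatures = n_temperatures
        self.temperature_ratio = temperature_ratio
        self.mc_prior_samples = mc_prior_samples
        self.max_clusters = max_clusters
        self.linkage = linkage
        self.random_state = random_state

    def fit(self, X, y=None, prior_pairs=None, gene_ids=None):
        """Cluster the rows of ``X`` (genes x samples).

        Parameters
        ----------
        X : array-like of shape (n_genes, n_samples)
            Log-scale expression; standardised internally per gene.
        prior_pairs : PriorSet or iterable of (gene_i, gene_j, p), optional
            Pairwise must-link priors; gene references are ids from
            ``gene_ids`` (or stringified row indices when omitted).
            A plain pair list is reduced to a forest automatically.
        gene_ids : sequence of str, optional
            Row identifiers; defaults to "0", "1", ...
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (genes x samples)")
        n_genes, n_samples = X.shape
        if n_genes < 2:
            raise ValueError("need at least 2 genes to cluster")
        if gene_ids is None:
            gene_ids = [str(i) for i in range(n_genes)]
        gene_ids = [str(g) for g in gene_ids]
        expr = ExpressionMatrix(
            values=X.T,
            gene_ids=gene_ids,
            sample_ids=[f"s{j}" for j in range(n_samples)],
        )
        expr = standardize(expr)
        M = self._coerce_prior(prior_pairs, gene_ids)
        config = SamplerConfig(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            n_temperatures=self.n_temperatures,
            temperature_ratio=self.temperature_ratio,
            mc_prior_samples=self.mc_prior_samples,
            seed=self._seed(),
        )
        rng = np.random.default_rng(config.seed)
        samples, trace = run_tempered(expr, M, config, rng)
        psm = posterior_similarity(samples)
        result = infer_clusters(psm, L=self.max_clusters, method=self.linkage)
        self.gene_ids_ = gene_ids
        self.samples_ = samples
        self.trace_ = trace
        self.posterior_similarity_ = psm.p
        self.labels_ = result.grouping.labels
        self.n_clusters_ = result.K_hat
        self.loss_curve_ = result.loss_curve
        self.n_features_in_ = n_samples
        return self

    def _seed(self) -> int | None:
        if self.random_state is None:
            return None
        if isinstance(self.random_state, numbers.Integral):
            return int(self.random_state)
        raise TypeError("random_state must be an int or None")

    @staticmethod
    def _coerce_prior(prior_pairs, gene_ids) -> PriorSet | None:
        if prior_pairs is None:
            return None
        if isinstance(prior_pairs, PriorSet):
            return prior_pairs
        pairs = [PriorPair(str(i), str(j), float(p)) for i, j, p in prior_pairs]
        prior_set, _ = remove_cycles(pairs, gene_universe=gene_ids)
        return prior_set

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_

    def __sklearn_is_fitted__(self):
        return hasattr(self, "labels_")

    @property
    def grouping_(self):
        check_is_fitted(self)
        from .partitions import Grouping

        return Grouping(self.labels_)
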