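"""Metropolis-Hastings kernel correctness: proposal normalisation,
reversibility, detailed balance, and chain reproducibility."""

import math
from collections import Counter

import numpy as np
import pytest

from mcip.likelihood import ExpressionMatrix, log_marginal_likelihood, standardize
from mcip.partitions import Grouping, enumerate_partitions
from mcip.prior_model import PriorPair, PriorSet, log_prior_exact, remove_cycles
from mcip.sampler import (
    SamplerConfig,
    acceptance_log_probability,
    ChainState,
    propose,
    proposal_distribution,
    run_chain,
    run_tempered,
)


def tiny_expr(n_genes, N, seed=0, duplicate_first_two=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(N, n_genes))
    if duplicate_first_two:
        X[:, 1] = X[:, 0] + 0.05 * rng.normal(size=N)
    return standardize(
        ExpressionMatrix(X, [f"g{i}" for i in range(n_genes)],
                         [f"s{j}" for j in range(N)])
    )


class TestProposalDistribution:
    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_forward_probabilities_sum_to_one(self, n):
        for g in enumerate_partitions(n):
            dist = proposal_distribution(g)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_two_singletons_only_merge(self):
        dist = proposal_distribution(Grouping([1, 2]))
        assert dist == {Grouping([1, 1]): pytest.approx(1.0)}

    def test_one_group_only_split(self):
        dist = proposal_distribution(Grouping([1, 1]))
        assert dist == {Grouping([1, 2]): pytest.approx(1.0)}

    def test_every_transition_has_a_reverse(self):
        """Structural reversibility: Q(g'|g) > 0 implies Q(g|g') > 0."""
        for g in enumerate_partitions(4):
            for g2, q in proposal_distribution(g).items():
                if q > 0:
                    back = proposal_distribution(g2)
                    assert back.get(g, 0.0) > 0


class TestPropose:
    def test_sampled_q_values_match_enumeration(self):
        """propose() must report exactly the Q(g'|g) and Q(g|g') that the
        exhaustive enumeration assigns to its outcome."""
        rng = np.random.default_rng(11)
        for labels in ([1, 1, 2, 3], [1, 1, 2, 2], [1, 2, 3, 4], [1, 1, 1, 1]):
            g = Grouping(labels)
            fwd = proposal_distribution(g)
            for _ in range(60):
                prop = propose(g, rng)
                assert math.exp(prop.log_q_forward) == pytest.approx(
                    fwd[prop.new_grouping], rel=1e-10
                )
                rev = proposal_distribution(prop.new_grouping)
                assert math.exp(prop.log_q_reverse) == pytest.approx(
                    rev[g], rel=1e-10
                )

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            propose(Grouping([1]), np.random.default_rng(0))

    def test_two_gene_split_is_certain(self):
        prop = propose(Grouping([1, 1]), np.random.default_rng(0))
        assert prop.move_type == "split"
        assert prop.log_q_forward == pytest.approx(0.0)
        assert prop.new_grouping == Grouping([1, 2])


class TestAcceptance:
    def test_symmetric_equal_mass_accepts_surely(self):
        state = ChainState(Grouping([1, 2]), log_lik=-3.0, log_prior=-1.0)
        from mcip.sampler import Proposal

        prop = Proposal(Grouping([1, 1]), "merge", -0.5, -0.5, [], [])
        assert acceptance_log_probability(state, prop, 0.0, 0.0) == 0.0

    def test_breaking_a_near_certain_pair_is_rejected(self):
        # prior ratio -> 0 when a p ~ 1 pair would be split
        universe = ["g0", "g1", "g2"]
        M, _ = remove_cycles([PriorPair("g0", "g1", 1 - 1e-12)], universe)
        gi = {g: i for i, g in enumerate(universe)}
        together = Grouping([1, 1, 2])
        apart = Grouping([1, 2, 3])
        delta = log_prior_exact(apart, M, gi) - log_prior_exact(together, M, gi)
        state = ChainState(together, 0.0, log_prior_exact(together, M, gi))
        from mcip.sampler import Proposal

        prop = Proposal(apart, "split", -1.0, -1.0, [], [])
        assert acceptance_log_probability(state, prop, 0.0, delta) < -20

    def test_detailed_balance_of_full_kernel(self):
        """pi_i P(i->j) = pi_j P(j->i) for the n=4 kernel, built exhaustively
        from the enumerated proposal distribution and the enumerated
        posterior (likelihood x pairwise prior)."""
        expr = tiny_expr(4, 12, seed=2)
        M, _ = remove_cycles([PriorPair("g0", "g1", 0.7)], list(expr.gene_ids))
        gi = expr.gene_index
        parts = enumerate_partitions(4)
        logpost = {
            g: log_marginal_likelihood(expr, g) + log_prior_exact(g, M, gi)
            for g in parts
        }
        for gi_ in parts:
            dist_i = proposal_distribution(gi_)
            for gj, q_ij in dist_i.items():
                q_ji = proposal_distribution(gj)[gi_]
                a_ij = min(
                    1.0,
                    math.exp(logpost[gj] - logpost[gi_]) * q_ji / q_ij,
                )
                a_ji = min(
                    1.0,
                    math.exp(logpost[gi_] - logpost[gj]) * q_ij / q_ji,
                )
                flow_ij = math.exp(logpost[gi_]) * q_ij * a_ij
                flow_ji = math.exp(logpost[gj]) * q_ji * a_ji
                assert flow_ij == pytest.approx(flow_ji, rel=1e-8)


class TestRunChain:
    def test_fixed_seed_reproducible(self):
        expr = tiny_expr(5, 10, seed=3)
        cfg = SamplerConfig(n_iterations=500, burn_in=100, thin=5,
                            n_temperatures=1, seed=9)
        s1, _ = run_chain(expr, None, cfg, np.random.default_rng(9))
        s2, _ = run_chain(expr, None, cfg, np.random.default_rng(9))
        assert s1 == s2

    def test_matches_enumerated_posterior(self):
        """Long-run frequencies on n=4 within total variation 0.05 of the
        exhaustively enumerated posterior."""
        expr = tiny_expr(4, 15, seed=5, duplicate_first_two=True)
        M, _ = remove_cycles([PriorPair("g2", "g3", 0.6)], list(expr.gene_ids))
        gi = expr.gene_index
        parts = enumerate_partitions(4)
        lp = np.array(
            [log_marginal_likelihood(expr, g) + log_prior_exact(g, M, gi)
             for g in parts]
        )
        post = np.exp(lp - lp.max())
        post /= post.sum()
        cfg = SamplerConfig(n_iterations=40_000, burn_in=4_000, thin=1,
                            n_temperatures=1, seed=1)
        samples, _ = run_chain(expr, M, cfg, np.random.default_rng(1))
        counts = Counter(samples)
        tv = 0.5 * sum(
            abs(counts.get(g, 0) / len(samples) - p) for g, p in zip(parts, post)
        )
        assert tv < 0.05

    def test_strong_prior_pair_cogrouped(self):
        expr = tiny_expr(5, 20, seed=6, duplicate_first_two=True)
        M, _ = remove_cycles([PriorPair("g0", "g1", 0.99)], list(expr.gene_ids))
        cfg = SamplerConfig(n_iterations=20_000, burn_in=2_000, thin=10,
                            n_temperatures=1, seed=2)
        samples, _ = run_chain(expr, M, cfg, np.random.default_rng(2))
        frac = np.mean([g.co_grouped(0, 1) for g in samples])
        assert frac > 0.9

    def test_cached_state_matches_fresh_evaluation(self):
        """After a run, the trace's cached log-likelihood and log-prior for
        the final state equal a from-scratch recomputation."""
        expr = tiny_expr(6, 12, seed=10)
        M, _ = remove_cycles(
            [PriorPair("g0", "g1", 0.8), PriorPair("g2", "g3", 0.5)],
            list(expr.gene_ids),
        )
        cfg = SamplerConfig(n_iterations=2000, burn_in=100, thin=1,
                            n_temperatures=1, seed=3)
        samples, trace = run_chain(expr, M, cfg, np.random.default_rng(3))
        final = samples[-1]  # thin=1: last sample is the final state
        gi = expr.gene_index
        assert trace[-1].log_lik == pytest.approx(
            log_marginal_likelihood(expr, final), abs=1e-8
        )
        assert trace[-1].log_prior == pytest.approx(
            log_prior_exact(final, M, gi), abs=1e-8
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)
        with pytest.raises(ValueError):
            SamplerConfig(temperature_ratio=1.5)


class TestTempering:
    def test_single_temperature_equals_plain_chain(self):
        expr = tiny_expr(5, 10, seed=3)
        cfg = SamplerConfig(n_iterations=400, burn_in=100, thin=5,
                            n_temperatures=1, seed=4)
        s1, _ = run_chain(expr, None, cfg, np.random.default_rng(4))
        s2, _ = run_tempered(expr, None, cfg, np.random.default_rng(4))
        assert s1 == s2

    def test_equal_beta_swap_always_accepted(self):
        # swap log-acceptance is (b_i - b_j)(logpi_j - logpi_i): zero when
        # the ladder is flat, so the swap is certain
        cfg = SamplerConfig(n_iterations=300, burn_in=50, thin=5,
                            n_temperatures=3, temperature_ratio=1.0, seed=5)
        expr = tiny_expr(4, 8, seed=8)
        samples, trace = run_tempered(expr, None, cfg, np.random.default_rng(5))
        assert all(t.swap for t in trace)

    def test_tempered_posterior_still_exact(self):
        """Cold-chain frequencies from a tempered run match the enumerated
        posterior: swaps must not bias the beta = 1 marginal."""
        from mcip.partitions import log_baseline_prior

        expr = tiny_expr(4, 15, seed=5, duplicate_first_two=True)
        parts = enumerate_partitions(4)
        lp = np.array(
            [log_marginal_likelihood(expr, g) + log_baseline_prior(g) for g in parts]
        )
        post = np.exp(lp - lp.max())
        post /= post.sum()
        cfg = SamplerConfig(n_iterations=40_000, burn_in=4_000, thin=1,
                            n_temperatures=3, temperature_ratio=0.6, seed=6)
        samples, _ = run_tempered(expr, None, cfg, np.random.default_rng(6))
        counts = Counter(samples)
        tv = 0.5 * sum(
            abs(counts.get(g, 0) / len(samples) - p) for g, p in zip(parts, post)
        )
        assert tv < 0.05
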