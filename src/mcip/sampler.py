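"""Metropolis-Hastings sampling over gene partitions.

The chain explores the space of groupings with three move types, each
proposed with probability 1/3 when admissible (splitting is impossible when
every group is a singleton, merging and moving when there is a single
group):

* **split** -- choose a non-singleton group with probability proportional
  to its size, then one of its ``N(n_k, 2)`` unordered bipartitions
  uniformly;
* **merge** -- choose a random gene (defining group ``k``), then another
  random gene re-sampled until it falls outside ``k`` (defining ``l``), and
  merge the two groups;
* **move**  -- choose a random gene re-sampled while it is a singleton
  (defining the source group ``l``), a random gene outside ``l`` (defining
  the target ``k``), and move a uniformly chosen member of ``l`` into ``k``.

A proposal ``g -> g'`` is accepted with probability

    min(1, [P(D|g') P(g'|M) / (P(D|g) P(g|M))]^beta * Q(g|g') / Q(g'|g)),

where ``beta`` is the chain's inverse temperature (1 for the cold chain).
Split and merge are mutual reverses; a move reverses itself.  Parallel
tempering runs several chains on powers of the posterior and lets adjacent
temperatures swap states, to escape local modes of the highly multimodal
partition posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .likelihood import ExpressionMatrix, GroupTermCache
from .partitions import Grouping, log_partition_count, sample_baseline_grouping
from .prior_model import ENUMERATION_GUARD, PriorSet, log_prior_exact, log_prior_mc

__all__ = [
    "Proposal",
    "ChainState",
    "SamplerConfig",
    "TraceRecord",
    "propose",
    "proposal_distribution",
    "acceptance_log_probability",
    "run_chain",
    "run_tempered",
]

logger = logging.getLogger(__name__)

_LOG_THIRD = -math.log(3.0)


@dataclass
class Proposal:
    """One proposed transition with forward/reverse proposal log-densities."""

    new_grouping: Grouping
    move_type: str  # "split" | "merge" | "move"
    log_q_forward: float
    log_q_reverse: float
    # member sets of the groups the move destroys / creates (for caching)
    old_groups: list[frozenset]
    new_groups: list[frozenset]


@dataclass
class ChainState:
    grouping: Grouping
    log_lik: float
    log_prior: float
    inverse_temperature: float = 1.0

    @property
    def log_posterior(self) -> float:
        return self.log_lik + self.log_prior


@dataclass
class SamplerConfig:
    """MCMC run lengths and tempering settings.

    Defaults mirror a full production run (150k iterations, 50k burn-in,
    every 100th sample kept, 200 Monte-Carlo draws for the prior when it
    cannot be enumerated); shorter values are fine for small instances.
    """

    n_iterations: int = 150_000
    burn_in: int = 50_000
    thin: int = 100
    n_temperatures: int = 4
    temperature_ratio: float = 0.7
    mc_prior_samples: int = 200
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_temperatures < 1:
            raise ValueError("n_temperatures must be >= 1")
        if not 0.0 < self.temperature_ratio <= 1.0:
            raise ValueError("temperature_ratio must be in (0, 1]")
        if self.mc_prior_samples < 1:
            raise ValueError("mc_prior_samples must be >= 1")


@dataclass
class TraceRecord:
    iteration: int
    log_lik: float
    log_prior: float
    K: int
    move_type: str
    accepted: bool
    chain: int = 0
    swap: bool = False


def _admissible_moves(K: int, n: int) -> list[str]:
    if K == 1:
        return ["split"]
    if K == n:
        return ["merge"]
    return ["split", "merge", "move"]


def _log_type_prob(K: int, n: int) -> float:
    return _LOG_THIRD if 1 < K < n else 0.0


def _group_sizes(g: Grouping) -> list[list[int]]:
    return g.groups()


def _merge_log_q(a: int, b: int, n: int, K: int) -> float:
    """log Q of merging two groups of sizes a, b (either pick order)."""
    q = (a / n) * (b / (n - a)) + (b / n) * (a / (n - b))
    return math.log(q) + _log_type_prob(K, n)


def _split_log_q(n_k: int, n: int, n_s: int, K: int) -> float:
    """log Q of one specific bipartition of a size-n_k group."""
    return (
        _log_type_prob(K, n)
        + math.log(n_k) - math.log(n - n_s)
        - log_partition_count(n_k, 2)
    )


def propose(g: Grouping, rng: np.random.Generator) -> Proposal:
    """Draw one split/merge/move proposal from grouping ``g``."""
    n, K = g.n, g.K
    if n < 2:
        raise ValueError("no admissible move for a single gene")
    groups = _group_sizes(g)
    sizes = np.array([len(m) for m in groups])
    n_s = int(np.sum(sizes == 1))
    moves = _admissible_moves(K, n)
    move = moves[int(rng.integers(0, len(moves)))]
    labels = g.labels.copy()

    if move == "split":
        nonsing = np.flatnonzero(sizes >= 2)
        weights = sizes[nonsing] / (n - n_s)
        k = int(nonsing[_weighted_choice(weights, rng)])
        members = groups[k]
        n_k = len(members)
        # uniform non-empty proper subset (unordered bipartition)
        while True:
            bits = rng.integers(0, 2, size=n_k)
            s = int(bits.sum())
            if 0 < s < n_k:
                break
        new_label = K + 1
        for i, b in zip(members, bits):
            if b:
                labels[i] = new_label
        part_a = frozenset(i for i, b in zip(members, bits) if b)
        part_b = frozenset(members) - part_a
        log_q_fwd = _split_log_q(n_k, n, n_s, K)
        log_q_rev = _merge_log_q(len(part_a), len(part_b), n, K + 1)
        return Proposal(
            Grouping(labels), "split", log_q_fwd, log_q_rev,
            old_groups=[frozenset(members)], new_groups=[part_a, part_b],
        )

    if move == "merge":
        gene_a = int(rng.integers(0, n))
        lab_a = g.labels[gene_a]
        while True:
            gene_b = int(rng.integers(0, n))
            if g.labels[gene_b] != lab_a:
                break
        lab_b = g.labels[gene_b]
        a, b = int(sizes[lab_a - 1]), int(sizes[lab_b - 1])
        labels[labels == lab_b] = lab_a
        merged = frozenset(groups[lab_a - 1]) | frozenset(groups[lab_b - 1])
        log_q_fwd = _merge_log_q(a, b, n, K)
        # reverse split in the merged state: K-1 groups, recount singletons
        n_s_new = n_s - (a == 1) - (b == 1)
        log_q_rev = _split_log_q(a + b, n, n_s_new, K - 1)
        return Proposal(
            Grouping(labels), "merge", log_q_fwd, log_q_rev,
            old_groups=[frozenset(groups[lab_a - 1]), frozenset(groups[lab_b - 1])],
            new_groups=[merged],
        )

    # move: source group l (non-singleton), target group k, uniform member
    while True:
        gene = int(rng.integers(0, n))
        lab_l = g.labels[gene]
        if sizes[lab_l - 1] >= 2:
            break
    while True:
        other = int(rng.integers(0, n))
        if g.labels[other] != lab_l:
            break
    lab_k = g.labels[other]
    n_l, n_k = int(sizes[lab_l - 1]), int(sizes[lab_k - 1])
    member = groups[lab_l - 1][int(rng.integers(0, n_l))]
    labels[member] = lab_k
    log_q_fwd = _LOG_THIRD + math.log(n_k) - math.log(n - n_s) - math.log(n - n_l)
    n_s_new = n_s + (n_l == 2) - (n_k == 1)
    log_q_rev = (
        _LOG_THIRD + math.log(n_l - 1) - math.log(n - n_s_new) - math.log(n - n_k - 1)
    )
    src = frozenset(groups[lab_l - 1])
    dst = frozenset(groups[lab_k - 1])
    return Proposal(
        Grouping(labels), "move", log_q_fwd, log_q_rev,
        old_groups=[src, dst], new_groups=[src - {member}, dst | {member}],
    )


def _weighted_choice(weights: np.ndarray, rng: np.random.Generator) -> int:
    u = rng.random() * weights.sum()
    return int(np.searchsorted(np.cumsum(weights), u, side="right"))


def proposal_distribution(g: Grouping) -> dict[Grouping, float]:
    """Exact forward-proposal distribution from ``g`` (small-n audits).

    Enumerates every (move type, choice) outcome with its probability;
    the values sum to 1 from every state.
    """
    n, K = g.n, g.K
    groups = _group_sizes(g)
    sizes = [len(m) for m in groups]
    n_s = sum(1 for s in sizes if s == 1)
    out: dict[Grouping, float] = {}

    def add(labels, p):
        gg = Grouping(labels)
        out[gg] = out.get(gg, 0.0) + p

    moves = _admissible_moves(K, n)
    for move in moves:
        if move == "split":
            for k, members in enumerate(groups):
                n_k = sizes[k]
                if n_k < 2:
                    continue
                p_each = math.exp(_split_log_q(n_k, n, n_s, K))
                for mask in range(1, 1 << (n_k - 1)):  # unordered bipartitions
                    labels = g.labels.copy()
                    for pos in range(n_k - 1):
                        if mask >> pos & 1:
                            labels[members[pos + 1]] = K + 1
                    add(labels, p_each)
        elif move == "merge":
            for ka in range(K):
                for kb in range(ka + 1, K):
                    labels = g.labels.copy()
                    labels[labels == kb + 1] = ka + 1
                    add(labels, math.exp(_merge_log_q(sizes[ka], sizes[kb], n, K)))
        else:
            for kl, members in enumerate(groups):
                n_l = sizes[kl]
                if n_l < 2:
                    continue
                for kk in range(K):
                    if kk == kl:
                        continue
                    p_each = (
                        (n_l / (n - n_s)) * (sizes[kk] / (n - n_l)) * (1 / n_l)
                    ) * math.exp(_log_type_prob(K, n))
                    for member in members:
                        labels = g.labels.copy()
                        labels[member] = kk + 1
                        add(labels, p_each)
    return out


class _PriorEvaluator:
    """Evaluates log P(g|M) exactly when q is small, by Monte Carlo otherwise."""

    def __init__(self, M: PriorSet, gene_index: dict[str, int],
                 mc_samples: int, rng: np.random.Generator):
        self.M = M
        self.gene_index = gene_index
        self.mc_samples = mc_samples
        self.rng = rng
        self.exact = M.q <= ENUMERATION_GUARD

    def __call__(self, g: Grouping) -> float:
        if self.exact:
            return log_prior_exact(g, self.M, self.gene_index)
        return log_prior_mc(g, self.M, self.mc_samples, self.rng, self.gene_index)


def acceptance_log_probability(
    current: ChainState, prop: Proposal, delta_log_lik: float, delta_log_prior: float
) -> float:
    """log of the Metropolis-Hastings acceptance probability."""
    beta = current.inverse_temperature
    return min(
        0.0,
        beta * (delta_log_lik + delta_log_prior)
        + prop.log_q_reverse
        - prop.log_q_forward,
    )


def _mh_step(
    state: ChainState,
    cache: GroupTermCache,
    prior_eval: _PriorEvaluator,
    rng: np.random.Generator,
) -> tuple[ChainState, str, bool]:
    prop = propose(state.grouping, rng)
    new_ll_terms = sum(cache.group_term(m) for m in prop.new_groups)
    old_ll_terms = sum(cache.group_term(m) for m in prop.old_groups)
    delta_ll = new_ll_terms - old_ll_terms
    if prior_eval.exact:
        new_lp = prior_eval(prop.new_grouping)
        old_lp = state.log_prior
    else:
        # fresh Monte-Carlo estimates for both states every step
        new_lp = prior_eval(prop.new_grouping)
        old_lp = prior_eval(state.grouping)
    log_alpha = acceptance_log_probability(state, prop, delta_ll, new_lp - old_lp)
    accept = math.log(rng.random()) < log_alpha
    if accept:
        state = ChainState(
            grouping=prop.new_grouping,
            log_lik=state.log_lik + delta_ll,
            log_prior=new_lp,
            inverse_temperature=state.inverse_temperature,
        )
    elif not prior_eval.exact:
        state = ChainState(state.grouping, state.log_lik, old_lp,
                           state.inverse_temperature)
    return state, prop.move_type, accept


def _init_state(
    expr: ExpressionMatrix,
    M: PriorSet,
    cache: GroupTermCache,
    prior_eval: _PriorEvaluator,
    rng: np.random.Generator,
    beta: float,
) -> ChainState:
    g = sample_baseline_grouping(expr.n_genes, rng)
    return ChainState(
        grouping=g,
        log_lik=cache.total(g),
        log_prior=prior_eval(g),
        inverse_temperature=beta,
    )


def run_chain(
    expr: ExpressionMatrix,
    M: PriorSet | None,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Grouping], list[TraceRecord]]:
    """Run a single cold chain; return thinned post-burn-in samples + trace.

    The trace logs every 100th iteration (and always the last) to keep its
    memory footprint small.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    M = _empty_prior(expr) if M is None else M
    cache = GroupTermCache(expr)
    prior_eval = _PriorEvaluator(M, expr.gene_index, config.mc_prior_samples, rng)
    state = _init_state(expr, M, cache, prior_eval, rng, beta=1.0)
    samples: list[Grouping] = []
    trace: list[TraceRecord] = []
    for it in range(1, config.n_iterations + 1):
        state, move, accepted = _mh_step(state, cache, prior_eval, rng)
        if it % 100 == 0 or it == config.n_iterations:
            trace.append(TraceRecord(it, state.log_lik, state.log_prior,
                                     state.grouping.K, move, accepted))
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            samples.append(state.grouping)
    return samples, trace


def _empty_prior(expr: ExpressionMatrix) -> PriorSet:
    return PriorSet(pairs=[], gene_universe=list(expr.gene_ids))


def run_tempered(
    expr: ExpressionMatrix,
    M: PriorSet | None,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[Grouping], list[TraceRecord]]:
    """Parallel tempering: geometric ladder beta_i = ratio^i, beta_0 = 1.

    Each sweep advances every chain one Metropolis-Hastings step, then one
    uniformly chosen adjacent pair proposes a state swap, accepted with
    probability min(1, exp((beta_i - beta_j) (log pi_j - log pi_i))) where
    log pi = log_lik + log_prior.  Only cold-chain (beta = 1) samples are
    returned.  With a single temperature this reduces to ``run_chain``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.n_temperatures == 1:
        return run_chain(expr, M, config, rng)
    M = _empty_prior(expr) if M is None else M
    cache = GroupTermCache(expr)
    prior_eval = _PriorEvaluator(M, expr.gene_index, config.mc_prior_samples, rng)
    betas = [config.temperature_ratio**i for i in range(config.n_temperatures)]
    states = [
        _init_state(expr, M, cache, prior_eval, rng, beta=b) for b in betas
    ]
    samples: list[Grouping] = []
    trace: list[TraceRecord] = []
    n_swap_attempts = 0
    n_swaps = 0
    for it in range(1, config.n_iterations + 1):
        moves_acc = []
        for c in range(len(states)):
            states[c], move, accepted = _mh_step(states[c], cache, prior_eval, rng)
            moves_acc.append((move, accepted))
        # one adjacent-pair swap attempt per sweep
        i = int(rng.integers(0, len(states) - 1))
        j = i + 1
        log_alpha = (betas[i] - betas[j]) * (
            states[j].log_posterior - states[i].log_posterior
        )
        n_swap_attempts += 1
        swapped = math.log(rng.random()) < min(0.0, log_alpha)
        if swapped:
            n_swaps += 1
            gi, gj = states[i], states[j]
            states[i] = ChainState(gj.grouping, gj.log_lik, gj.log_prior, betas[i])
            states[j] = ChainState(gi.grouping, gi.log_lik, gi.log_prior, betas[j])
        if it % 100 == 0 or it == config.n_iterations:
            move, accepted = moves_acc[0]
            trace.append(TraceRecord(it, states[0].log_lik, states[0].log_prior,
                                     states[0].grouping.K, move, accepted,
                                     chain=0, swap=swapped))
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            samples.append(states[0].grouping)
    if n_swap_attempts:
        logger.info(
            "parallel tempering: %d/%d swaps accepted (%.1f%%)",
            n_swaps, n_swap_attempts, 100.0 * n_swaps / n_swap_attempts,
        )
    return samples, trace
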