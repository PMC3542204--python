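"""Metropolis-coupled MCMC over DAG structures.

``run_mc3`` drives the compiled kernel: several tempered chains with
periodic state-swap proposals, cold-chain samples recorded after burn-in at
the thinning interval, and feature-indicator traces evaluated per
independent replicate for convergence diagnostics.  The pure-Python
``enumerate_moves`` / ``mh_step`` / ``swap_step`` operations define the
reference semantics of one sampler step and back the unit tests; the
kernel implements the same proposal, score and acceptance rule.

Scaled-down defaults (4 chains, 5e4 burn-in, 2e5 steps, thinning 10) are a
desk-scale surrogate for production protocols that run tens of millions of
steps; all counts are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kernel import MAX_KERNEL_VARS, run_mc3_kernel
from .dataset import DiscreteDataset
from .diagnostics import ConvergenceReport, gelman_rubin, geweke_z
from .features import FeatureQuery, query_indicator_stack
from .scoring import FamilyScoreCache, ScoreConfig, family_log_score, log_structure_prior
from .structure import DAGStructure, is_acyclic, transitive_closure


@dataclass
class SamplerConfig:
    """MC3 protocol: chain count, temperature ladder and step counts.

    ``temperature_ladder`` holds inverse-temperature exponents, cold chain
    first and exactly 1; the default is geometric with ratio 0.7.
    ``n_replicates`` independent cold-chain replicates are run (each with
    its own seeded stream) so Gelman-Rubin diagnostics are available.
    """

    n_chains: int = 4
    temperature_ladder: tuple[float, ...] = (1.0, 0.7, 0.49, 0.343)
    burn_in_steps: int = 50_000
    sample_steps: int = 200_000
    thinning: int = 10
    swap_interval: int = 10
    max_in_degree: int = 4
    n_replicates: int = 3
    seed: int = 0
    structure_prior: str = "uniform_dags"

    def __post_init__(self) -> None:
        if self.n_chains < 1 or len(self.temperature_ladder) != self.n_chains:
            raise ValueError("temperature ladder length must equal n_chains")
        if self.temperature_ladder[0] != 1.0:
            raise ValueError("cold chain exponent must be exactly 1")
        if any(b <= 0 for b in self.temperature_ladder):
            raise ValueError("inverse temperatures must be positive")
        if list(self.temperature_ladder) != sorted(self.temperature_ladder, reverse=True):
            raise ValueError("ladder must be ordered cold (1.0) to hot")
        if self.burn_in_steps < 0 or self.sample_steps < 0:
            raise ValueError("step counts must be >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    def score_config(self) -> ScoreConfig:
        return ScoreConfig(structure_prior=self.structure_prior, max_in_degree=self.max_in_degree)

    def scaled(self, factor: float) -> "SamplerConfig":
        """Multiply burn-in and sample steps by ``factor`` (chain-scale knob)."""
        return replace(
            self,
            burn_in_steps=max(1, int(self.burn_in_steps * factor)),
            sample_steps=max(self.thinning, int(self.sample_steps * factor)),
        )


@dataclass
class StructureSample:
    """Cold-chain posterior structure samples, stacked across replicates."""

    names: list[str]
    replicate_stacks: list[np.ndarray]  # each (S_i, n, n) bool
    accept_rates: np.ndarray | None = None  # (replicates, chains)
    swap_rates: np.ndarray | None = None
    final_scores: np.ndarray | None = None

    def adjacency_stack(self) -> np.ndarray:
        return np.concatenate(self.replicate_stacks, axis=0)

    @property
    def n_samples(self) -> int:
        return sum(len(s) for s in self.replicate_stacks)

    def edge_posteriors(self) -> np.ndarray:
        """(n, n) posterior probability of each directed edge."""
        return self.adjacency_stack().mean(axis=0)


def _masks_to_adjacency(rec: np.ndarray, n: int) -> np.ndarray:
    # rec[s, v] = parent bitmask of node v; adj[s, u, v] = bit u of rec[s, v]
    shifts = np.arange(n, dtype=np.int64)[None, :, None]
    return ((rec[:, None, :] >> shifts) & 1).astype(bool)


def run_mc3(
    dataset: DiscreteDataset,
    config: SamplerConfig | None = None,
    feature_set: Sequence[FeatureQuery] | None = None,
) -> tuple[StructureSample, dict[str, np.ndarray], ConvergenceReport]:
    """Sample the structure posterior and evaluate feature traces.

    Returns the pooled cold-chain samples, a mapping feature label ->
    (replicates, samples) indicator traces, and a per-feature convergence
    report (Gelman-Rubin across replicates when >= 2, Geweke within each).
    Fully reproducible for a given config.
    """
    config = config or SamplerConfig()
    if config.sample_steps < config.thinning:
        raise ValueError("sample_steps must allow at least one recorded sample")
    n = dataset.n_variables
    if n > MAX_KERNEL_VARS:
        raise ValueError(f"sampler supports at most {MAX_KERNEL_VARS} variables; reduce to tag SNPs")
    matrix = dataset.matrix()
    arities = dataset.arity_vector()
    betas = np.asarray(config.temperature_ladder, dtype=np.float64)
    prior_parent_size = 1 if config.structure_prior == "parent_set_size" else 0
    from scipy.special import gammaln

    sizes = np.arange(n, dtype=float)
    logc = -(gammaln(n) - gammaln(sizes + 1) - gammaln(n - sizes))  # -ln C(n-1, k)

    stacks: list[np.ndarray] = []
    accept_rates = np.zeros((config.n_replicates, config.n_chains))
    swap_rates = np.zeros(config.n_replicates)
    finals = np.zeros((config.n_replicates, config.n_chains))
    for rep in range(config.n_replicates):
        rep_seed = int((config.seed * 1_000 + rep + 1) % (2**31 - 1))
        rec, acc, prop, sacc, sprop, scores = run_mc3_kernel(
            matrix,
            arities,
            config.max_in_degree,
            betas,
            config.burn_in_steps,
            config.sample_steps,
            config.thinning,
            config.swap_interval,
            rep_seed,
            prior_parent_size,
            logc,
        )
        adj = _masks_to_adjacency(rec, n)
        _validate_samples(adj, config.max_in_degree)
        stacks.append(adj)
        with np.errstate(invalid="ignore", divide="ignore"):
            accept_rates[rep] = np.where(prop > 0, acc / np.maximum(prop, 1), 0.0)
        swap_rates[rep] = sacc / sprop if sprop else 0.0
        finals[rep] = scores

    sample = StructureSample(
        names=list(dataset.variable_names),
        replicate_stacks=stacks,
        accept_rates=accept_rates,
        swap_rates=swap_rates,
        final_scores=finals,
    )

    traces: dict[str, np.ndarray] = {}
    report = ConvergenceReport()
    for query in feature_set or []:
        per_rep = np.stack(
            [query_indicator_stack(stack, sample.names, query).astype(np.int8) for stack in stacks]
        )
        traces[query.label()] = per_rep
        if config.n_replicates >= 2:
            report.r_scores[query.label()] = gelman_rubin(per_rep)
        zs = []
        for row in per_rep:
            if row.size >= 20:
                zs.append(geweke_z(row))
        report.geweke_scores[query.label()] = zs
    return sample, traces, report


def _validate_samples(adj: np.ndarray, max_in_degree: int) -> None:
    # online invariants: every sampled structure acyclic and in-degree bounded
    if adj.sum(axis=1).max(initial=0) > max_in_degree:
        raise AssertionError("sampled structure violates the in-degree bound")
    reach = adj.astype(np.uint8)
    n = adj.shape[-1]
    for _ in range(max(1, int(np.ceil(np.log2(max(n, 2)))))):
        reach = np.minimum(reach + np.matmul(reach, reach), 1)
    if np.any(reach[:, np.arange(n), np.arange(n)]):
        raise AssertionError("sampled structure contains a cycle")


# ---------------------------------------------------------------------------
# Pure-Python reference operations (one sampler step)
# ---------------------------------------------------------------------------


def enumerate_moves(structure: DAGStructure) -> list[tuple[str, tuple[int, int]]]:
    """All single-edge moves preserving acyclicity and the in-degree bound.

    Move kinds are ``add``/``delete``/``reverse`` with the edge (u, v) in
    its pre-move orientation.
    """
    adj = structure.adjacency()
    n = structure.n_nodes
    reach = transitive_closure(adj)
    indeg = adj.sum(axis=0)
    maxp = structure.max_in_degree
    moves: list[tuple[str, tuple[int, int]]] = []
    for u in range(n):
        for v in range(n):
            if u == v:
                continue
            if adj[u, v]:
                moves.append(("delete", (u, v)))
                if indeg[u] < maxp:
                    others = adj[u].copy()
                    others[v] = False
                    if not np.any(others & reach[:, v]):
                        moves.append(("reverse", (u, v)))
            elif indeg[v] < maxp and not reach[v, u]:
                moves.append(("add", (u, v)))
    return moves


def apply_move(structure: DAGStructure, move: tuple[str, tuple[int, int]]) -> DAGStructure:
    kind, (u, v) = move
    parents = [set(ps) for ps in structure.parent_sets]
    if kind == "add":
        parents[v].add(u)
    elif kind == "delete":
        parents[v].discard(u)
    elif kind == "reverse":
        parents[v].discard(u)
        parents[u].add(v)
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    return DAGStructure(
        structure.node_names, [tuple(sorted(p)) for p in parents], structure.max_in_degree
    )


@dataclass
class ChainState:
    structure: DAGStructure
    log_score: float  # log marginal likelihood + log structure prior


def chain_state(
    dataset: DiscreteDataset,
    structure: DAGStructure,
    config: ScoreConfig | None = None,
    cache: FamilyScoreCache | None = None,
) -> ChainState:
    config = config or ScoreConfig()
    total = sum(
        family_log_score(v, ps, dataset, cache) for v, ps in enumerate(structure.parent_sets)
    )
    return ChainState(structure, total + log_structure_prior(structure, config))


def mh_step(
    state: ChainState,
    dataset: DiscreteDataset,
    rng: np.random.Generator,
    inverse_temperature: float = 1.0,
    config: ScoreConfig | None = None,
    cache: FamilyScoreCache | None = None,
) -> tuple[ChainState, bool]:
    """One Metropolis-Hastings step with the uniform single-edge proposal.

    Acceptance: ``min{1, exp(beta * delta) * |moves(G)| / |moves(G')|}``
    where delta is the change in log score plus log prior — the
    neighbourhood ratio corrects for the asymmetric proposal.
    """
    config = config or ScoreConfig()
    moves = enumerate_moves(state.structure)
    if not moves:
        return state, False
    move = moves[rng.integers(len(moves))]
    proposal = apply_move(state.structure, move)
    new_state = chain_state(dataset, proposal, config, cache)
    m1 = len(moves)
    m2 = len(enumerate_moves(proposal))
    log_alpha = inverse_temperature * (new_state.log_score - state.log_score) + np.log(m1 / m2)
    if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
        return new_state, True
    return state, False


def swap_step(
    state_i: ChainState,
    state_j: ChainState,
    beta_i: float,
    beta_j: float,
    rng: np.random.Generator,
) -> tuple[ChainState, ChainState, bool]:
    """Tempered-state exchange between adjacent chains.

    Accepted with ``min{1, exp((beta_i - beta_j)(s_j - s_i))}`` where s is
    the (untempered) log score plus log prior of each chain's state.
    """
    log_alpha = (beta_i - beta_j) * (state_j.log_score - state_i.log_score)
    if log_alpha >= 0 or np.log(rng.random()) < log_alpha:
        return state_j, state_i, True
    return state_i, state_j, False
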