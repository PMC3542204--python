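"""Brute-force structure-posterior oracle for small variable sets.

Enumerates every DAG over at most five variables (3^(n choose 2) edge-state
assignments filtered for acyclicity and the in-degree bound), scores each
with the same K2 score and structure prior as the sampler, and computes
exact feature posteriors by full summation.  This is the independent ground
truth the MCMC sampler is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.special import logsumexp

from .dataset import DiscreteDataset
from .features import FeatureQuery, query_indicator_stack
from .scoring import FamilyScoreCache, ScoreConfig, family_log_score, log_structure_prior
from .structure import DAGStructure, is_acyclic

MAX_ORACLE_NODES = 5

# unconstrained DAG counts (Robinson's recurrence) for sanity checks
ROBINSON_COUNTS = {0: 1, 1: 1, 2: 3, 3: 25, 4: 543, 5: 29281}


def enumerate_dags(n_nodes: int, max_in_degree: int = 4) -> np.ndarray:
    """All allowed DAGs as an (n_graphs, n, n) boolean adjacency stack.

    Iterates the three states (absent, forward, backward) of every node
    pair, filtering cyclic graphs and in-degree violations.  Refuses more
    than five nodes — the oracle exists to be obviously correct, not fast.
    """
    if n_nodes > MAX_ORACLE_NODES:
        raise ValueError(f"oracle enumeration capped at {MAX_ORACLE_NODES} nodes")
    pairs = list(combinations(range(n_nodes), 2))
    graphs = []
    for states in product((0, 1, 2), repeat=len(pairs)):
        adj = np.zeros((n_nodes, n_nodes), dtype=bool)
        for (i, j), s in zip(pairs, states):
            if s == 1:
                adj[i, j] = True
            elif s == 2:
                adj[j, i] = True
        if adj.sum(axis=0).max(initial=0) > max_in_degree:
            continue
        if not is_acyclic(adj):
            continue
        graphs.append(adj)
    return np.array(graphs, dtype=bool)


@dataclass
class EnumerationResult:
    """Exhaustively enumerated structures with normalized posterior weights."""

    structures: np.ndarray  # (B, n, n) bool
    log_weights: np.ndarray  # normalized: logsumexp == 0
    names: list[str]

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def adjacency_stack(self) -> np.ndarray:
        return self.structures


def enumerate_posterior(
    dataset: DiscreteDataset, config: ScoreConfig | None = None
) -> EnumerationResult:
    """Exact normalized structure posterior over all allowed DAGs."""
    config = config or ScoreConfig()
    names = dataset.variable_names
    n = len(names)
    graphs = enumerate_dags(n, config.max_in_degree)
    cache = FamilyScoreCache()
    log_w = np.empty(len(graphs))
    for g, adj in enumerate(graphs):
        total = 0.0
        for v in range(n):
            parents = tuple(np.nonzero(adj[:, v])[0].tolist())
            total += family_log_score(v, parents, dataset, cache)
        structure = DAGStructure.from_adjacency(names, adj, config.max_in_degree)
        total += log_structure_prior(structure, config)
        log_w[g] = total
    log_w -= logsumexp(log_w)
    return EnumerationResult(structures=graphs, log_weights=log_w, names=list(names))


def exact_posterior(
    dataset: DiscreteDataset,
    query: FeatureQuery,
    config: ScoreConfig | None = None,
    enumeration: EnumerationResult | None = None,
) -> float:
    """P(feature | D) by exact summation over all allowed structures."""
    if enumeration is None:
        enumeration = enumerate_posterior(dataset, config)
    indicator = query_indicator_stack(enumeration.structures, enumeration.names, query)
    return float(np.sum(enumeration.weights[indicator]))
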