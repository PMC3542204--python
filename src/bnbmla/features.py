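"""Structural-relevance features of sampled DAGs and their posteriors.

The feature taxonomy distinguishes how a variable X can relate to the
target Y in a network structure:

- ``DCR`` — direct relevance: an edge between X and Y (either orientation);
- ``TCR`` — transitive relevance: a directed path of length >= 2 between
  X and Y (either direction), i.e. mediation;
- ``ConfR`` — confounded relevance: X and Y share a common ancestor;
- ``A`` — association: DCR or TCR or ConfR;
- ``PIR`` — pure interactionist relevance: X and Y share a child;
- ``SR`` — strong relevance: DCR or PIR, equivalently membership of X in
  the Markov blanket of Y.

Averaging a feature's indicator over posterior structure samples gives its
posterior probability; joint (set) strong relevance underlies the
interaction/redundancy ratio: R above 1 marks variables that enter the
Markov blanket together more often than independence predicts, R below 1
marks interchangeable (redundant) variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .diagnostics import effective_sample_size
from .structure import DAGStructure

PAIRWISE_KINDS = ("DCR", "DCR_directed", "TCR", "ConfR", "A", "PIR", "SR")
SET_KINDS = ("MBS_membership", "MBS_identity", "MBG_identity")

RELEVANCE_MODERATE = 0.5
RELEVANCE_CONVINCING = 0.75


@dataclass(frozen=True)
class FeatureQuery:
    """A structural feature to evaluate against the designated target."""

    kind: str
    variables: tuple[str, ...]
    target: str
    subgraph_edges: frozenset[tuple[str, str]] | None = None  # MBG_identity only

    def __post_init__(self) -> None:
        if self.kind not in PAIRWISE_KINDS + SET_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.target in self.variables and self.kind != "MBS_identity":
            raise ValueError("target cannot also be a query variable")

    def label(self) -> str:
        return f"{self.kind}({','.join(self.variables)};{self.target})"


@dataclass
class RelevancePosterior:
    """Posterior of one feature with its Monte-Carlo error and class label."""

    query: FeatureQuery
    posterior: float
    mc_standard_error: float
    n_samples: int
    n_effective: float

    @property
    def classification(self) -> str:
        if self.posterior > RELEVANCE_CONVINCING:
            return "convincing"
        if self.posterior >= RELEVANCE_MODERATE:
            return "moderate"
        return "not relevant"


@dataclass
class InteractionResult:
    """Interaction/redundancy ratio of a variable set against the target."""

    variables: tuple[str, ...]
    joint_posterior: float
    singleton_posteriors: dict[str, float]
    ratio: float | None  # None when a singleton posterior is 0
    interaction_ratio: float = 0.0  # ln R when R > 1
    redundancy_ratio: float = 0.0  # -ln R when R < 1

    @property
    def undefined(self) -> bool:
        return self.ratio is None


# ---------------------------------------------------------------------------
# Vectorized feature evaluation on stacks of adjacency matrices
# ---------------------------------------------------------------------------


def closure_stack(adj: np.ndarray) -> np.ndarray:
    """Batched reachability (length >= 1) for an (S, n, n) adjacency stack."""
    reach = adj.astype(np.uint8)
    n = adj.shape[-1]
    for _ in range(max(1, int(np.ceil(np.log2(max(n, 2)))))):
        new = np.minimum(reach + np.matmul(reach, reach), 1)
        if np.array_equal(new, reach):
            break
        reach = new
    return reach.astype(bool)


def markov_blanket_stack(adj: np.ndarray, t: int) -> np.ndarray:
    """(S, n) membership of each variable in the Markov blanket of node t."""
    a = adj.astype(np.uint8)
    parents = adj[:, :, t]
    children = adj[:, t, :]
    spouses = np.matmul(a, a[:, t, :][..., None])[..., 0] > 0  # share a child with t
    mb = parents | children | spouses
    mb[:, t] = False
    return mb


def pairwise_feature_stack(adj: np.ndarray, kind: str, x: int, y: int) -> np.ndarray:
    """(S,) boolean indicator of a pairwise feature between nodes x and y."""
    a = adj.astype(np.uint8)
    if kind == "DCR":
        return adj[:, x, y] | adj[:, y, x]
    if kind == "DCR_directed":
        return adj[:, x, y]
    reach = closure_stack(adj).astype(np.uint8)
    if kind == "TCR":
        two_plus = np.matmul(a, reach)  # paths of length >= 2
        return (two_plus[:, x, y] > 0) | (two_plus[:, y, x] > 0)
    if kind == "ConfR":
        common = np.matmul(reach.transpose(0, 2, 1), reach)  # shared proper ancestor
        return common[:, x, y] > 0
    if kind == "PIR":
        common_child = np.matmul(a, a.transpose(0, 2, 1))
        return common_child[:, x, y] > 0
    if kind == "A":
        return (
            pairwise_feature_stack(adj, "DCR", x, y)
            | pairwise_feature_stack(adj, "TCR", x, y)
            | pairwise_feature_stack(adj, "ConfR", x, y)
        )
    if kind == "SR":
        return pairwise_feature_stack(adj, "DCR", x, y) | pairwise_feature_stack(adj, "PIR", x, y)
    raise ValueError(f"unknown pairwise kind {kind!r}")


def query_indicator_stack(adj: np.ndarray, names: Sequence[str], query: FeatureQuery) -> np.ndarray:
    """(S,) indicator trace of any feature query over an adjacency stack."""
    idx = {name: i for i, name in enumerate(names)}
    t = idx[query.target]
    if query.kind in PAIRWISE_KINDS:
        (xv,) = query.variables
        return pairwise_feature_stack(adj, query.kind, idx[xv], t).astype(bool)
    mb = markov_blanket_stack(adj, t)
    if query.kind == "MBS_membership":
        cols = [idx[v] for v in query.variables]
        return mb[:, cols].all(axis=1)
    if query.kind == "MBS_identity":
        want = np.zeros(len(names), dtype=bool)
        for v in query.variables:
            want[idx[v]] = True
        want[t] = False
        return (mb == want[None, :]).all(axis=1)
    if query.kind == "MBG_identity":
        if query.subgraph_edges is None:
            raise ValueError("MBG_identity requires subgraph_edges")
        want = np.zeros(adj.shape[1:], dtype=bool)
        for p, c in query.subgraph_edges:
            want[idx[p], idx[c]] = True
        mbg = _mbg_edges_stack(adj, t)
        return (mbg == want[None, :, :]).all(axis=(1, 2))
    raise ValueError(f"unknown kind {query.kind!r}")


def _mbg_edges_stack(adj: np.ndarray, t: int) -> np.ndarray:
    """(S, n, n) edge masks of the Markov blanket subgraph of node t:
    edges into t and into each child of t."""
    S, n, _ = adj.shape
    into = np.zeros_like(adj)
    into[:, :, t] = adj[:, :, t]
    children = adj[:, t, :]  # (S, n)
    into |= adj & children[:, None, :]
    return into


# ---------------------------------------------------------------------------
# Single-structure operations
# ---------------------------------------------------------------------------


def feature_indicator(structure: DAGStructure, query: FeatureQuery) -> int:
    """Evaluate one feature on one DAG; returns 0 or 1."""
    adj = structure.adjacency()[None, :, :]
    return int(query_indicator_stack(adj, structure.node_names, query)[0])


def markov_blanket(structure: DAGStructure, target: str) -> set[str]:
    """Parents, children and co-parents of children of the target."""
    t = structure.node_names.index(target)
    mb = markov_blanket_stack(structure.adjacency()[None, :, :], t)[0]
    return {structure.node_names[i] for i in np.nonzero(mb)[0]}


def markov_blanket_subgraph(structure: DAGStructure, target: str) -> DAGStructure:
    """Sub-DAG over MBS plus the target: edges into the target and into its
    children (the interaction model of the strongly relevant variables)."""
    t = structure.node_names.index(target)
    adj = structure.adjacency()
    edges_mask = _mbg_edges_stack(adj[None, :, :], t)[0]
    nodes = sorted(markov_blanket(structure, target) | {target}, key=structure.node_names.index)
    idx = {name: i for i, name in enumerate(structure.node_names)}
    edges = [
        (structure.node_names[u], structure.node_names[v])
        for u, v in zip(*np.nonzero(edges_mask))
    ]
    return DAGStructure.from_edges(nodes, edges, structure.max_in_degree)


# ---------------------------------------------------------------------------
# Posteriors over samples
# ---------------------------------------------------------------------------


def posterior_from_trace(trace: np.ndarray, query: FeatureQuery) -> RelevancePosterior:
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty sample collection")
    p = float(trace.mean())
    n_eff = effective_sample_size(trace)
    se = float(np.sqrt(max(p * (1.0 - p), 0.0) / n_eff))
    return RelevancePosterior(
        query=query, posterior=p, mc_standard_error=se, n_samples=trace.size, n_effective=n_eff
    )


def posterior(samples, query: FeatureQuery) -> RelevancePosterior:
    """Posterior of a feature over cold-chain structure samples.

    ``samples`` is anything with ``.adjacency_stack()`` and ``.names``
    (a :class:`bnbmla.sampler.StructureSample`) or a bare (S, n, n) array
    plus names via :func:`posterior_from_stack`.
    """
    return posterior_from_stack(samples.adjacency_stack(), samples.names, query)


def posterior_from_stack(adj: np.ndarray, names: Sequence[str], query: FeatureQuery) -> RelevancePosterior:
    trace = query_indicator_stack(adj, names, query)
    return posterior_from_trace(trace, query)


def subrelevance_posterior(samples, variable_set: Sequence[str], target: str) -> float:
    """Posterior that the whole set lies inside the target's Markov blanket.

    Equals the MBS-identity posterior of the set plus the posteriors of all
    its supersets, computed directly as the fraction of samples whose MBS
    contains the set.
    """
    variable_set = tuple(variable_set)
    if not variable_set:
        raise ValueError("variable set must be non-empty")
    if target in variable_set:
        raise ValueError("variable set must exclude the target")
    q = FeatureQuery(kind="MBS_membership", variables=variable_set, target=target)
    adj, names = _stack_and_names(samples)
    return float(query_indicator_stack(adj, names, q).mean())


def interaction_ratio(samples, variable_set: Sequence[str], target: str) -> InteractionResult:
    """Interaction (ln R > 0) or redundancy (ln R < 0) of a variable set.

    ``R`` is the joint sub-relevance posterior over the product of the
    singleton sub-relevance posteriors.  A singleton posterior of zero
    leaves the ratio undefined (flagged, not raised).
    """
    variable_set = tuple(variable_set)
    joint = subrelevance_posterior(samples, variable_set, target)
    singles = {v: subrelevance_posterior(samples, (v,), target) for v in variable_set}
    if len(variable_set) == 1:
        return InteractionResult(variable_set, joint, singles, ratio=1.0)
    denom = float(np.prod(list(singles.values())))
    if denom == 0.0:
        return InteractionResult(variable_set, joint, singles, ratio=None)
    r = joint / denom
    log_r = np.log(r) if r > 0 else float("-inf")
    return InteractionResult(
        variable_set,
        joint,
        singles,
        ratio=float(r),
        interaction_ratio=float(log_r) if log_r > 0 else 0.0,
        redundancy_ratio=float(-log_r) if log_r < 0 else 0.0,
    )


def _stack_and_names(samples) -> tuple[np.ndarray, Sequence[str]]:
    if isinstance(samples, tuple):
        return samples
    return samples.adjacency_stack(), samples.names
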