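"""Directed acyclic graph hypothesis objects with a bounded in-degree.

A structure is the hypothesis G of the Bayesian score: node names, one
parent set per node, and the in-degree bound that defines the search space
(default 4 parents per node).  Serialization is a plain edge-list text
format, one ``parent<TAB>child`` per line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

DEFAULT_MAX_IN_DEGREE = 4


@dataclass
class DAGStructure:
    node_names: list[str]
    parent_sets: list[tuple[int, ...]] = field(default_factory=list)
    max_in_degree: int = DEFAULT_MAX_IN_DEGREE

    def __post_init__(self) -> None:
        n = len(self.node_names)
        if not self.parent_sets:
            self.parent_sets = [() for _ in range(n)]
        if len(self.parent_sets) != n:
            raise ValueError("one parent set per node required")
        self.parent_sets = [tuple(sorted(ps)) for ps in self.parent_sets]
        for v, ps in enumerate(self.parent_sets):
            if v in ps:
                raise ValueError(f"node {self.node_names[v]} is its own parent")
            if any(p < 0 or p >= n for p in ps):
                raise ValueError("parent index out of range")

    # -- construction ---------------------------------------------------

    @staticmethod
    def empty(node_names: Sequence[str], max_in_degree: int = DEFAULT_MAX_IN_DEGREE) -> "DAGStructure":
        return DAGStructure(list(node_names), [()] * len(node_names), max_in_degree)

    @staticmethod
    def from_edges(
        node_names: Sequence[str],
        edges: Iterable[tuple[str, str]],
        max_in_degree: int = DEFAULT_MAX_IN_DEGREE,
    ) -> "DAGStructure":
        idx = {name: i for i, name in enumerate(node_names)}
        parents: list[list[int]] = [[] for _ in node_names]
        for parent, child in edges:
            parents[idx[child]].append(idx[parent])
        return DAGStructure(list(node_names), [tuple(sorted(p)) for p in parents], max_in_degree)

    @staticmethod
    def from_adjacency(
        node_names: Sequence[str],
        adjacency: np.ndarray,
        max_in_degree: int = DEFAULT_MAX_IN_DEGREE,
    ) -> "DAGStructure":
        adj = np.asarray(adjacency, dtype=bool)
        parents = [tuple(np.nonzero(adj[:, v])[0].tolist()) for v in range(len(node_names))]
        return DAGStructure(list(node_names), parents, max_in_degree)

    # -- views -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def adjacency(self) -> np.ndarray:
        """Boolean matrix with ``adj[u, v]`` true for edge u -> v."""
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for v, ps in enumerate(self.parent_sets):
            for p in ps:
                adj[p, v] = True
        return adj

    def edges(self) -> list[tuple[str, str]]:
        return [
            (self.node_names[p], self.node_names[v])
            for v, ps in enumerate(self.parent_sets)
            for p in ps
        ]

    def in_degree_ok(self) -> bool:
        return all(len(ps) <= self.max_in_degree for ps in self.parent_sets)

    # -- serialization ---------------------------------------------------

    def to_edge_list(self) -> str:
        lines = [f"{p}\t{c}" for p, c in sorted(self.edges())]
        return "\n".join(lines) + ("\n" if lines else "")

    @staticmethod
    def from_edge_list(
        text: str,
        node_names: Sequence[str],
        max_in_degree: int = DEFAULT_MAX_IN_DEGREE,
    ) -> "DAGStructure":
        edges = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            parent, child = line.split("\t")
            edges.append((parent, child))
        return DAGStructure.from_edges(node_names, edges, max_in_degree)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_edge_list())


def is_acyclic(structure: DAGStructure | np.ndarray) -> bool:
    """True iff a topological order exists (Kahn's algorithm)."""
    adj = structure.adjacency() if isinstance(structure, DAGStructure) else np.asarray(structure, bool)
    n = adj.shape[0]
    indeg = adj.sum(axis=0).astype(int)
    stack = [v for v in range(n) if indeg[v] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for v in np.nonzero(adj[u])[0]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == n


def transitive_closure(adj: np.ndarray) -> np.ndarray:
    """Reachability by paths of length >= 1, via boolean matrix squaring."""
    reach = adj.astype(bool).copy()
    n = adj.shape[0]
    steps = max(1, int(np.ceil(np.log2(max(n, 2)))))
    for _ in range(steps):
        new = reach | (reach @ reach)
        if np.array_equal(new, reach):
            break
        reach = new
    return reach
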