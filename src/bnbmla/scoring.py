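"""Closed-form Bayesian score: Dirichlet-multinomial marginal likelihood
with the K2 (all-ones) hyperparameter prior, plus the structure prior.

For a node with arity ``r`` and parent configurations ``j`` with genotype
counts ``N_jk`` (``N_j`` their sum), the log family score is

    sum_j [ ln G(r) - ln G(r + N_j) + sum_k ln G(1 + N_jk) ]

with ``G`` the gamma function — the Cooper-Herskovits closed form with unit
hyperparameters.  The total log marginal likelihood decomposes over
families, which the per-family LRU cache exploits: structure MCMC revisits
the same families constantly.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy.special import binom, gammaln

from .dataset import DiscreteDataset
from .structure import DAGStructure, is_acyclic


@dataclass
class ScoreConfig:
    """Score and prior configuration shared by sampler and oracle."""

    prior_kind: str = "K2"
    structure_prior: str = "uniform_dags"  # or "parent_set_size"
    max_in_degree: int = 4

    def __post_init__(self) -> None:
        if self.prior_kind != "K2":
            raise ValueError(f"unsupported parameter prior {self.prior_kind!r}")
        if self.structure_prior not in ("uniform_dags", "parent_set_size"):
            raise ValueError(f"unsupported structure prior {self.structure_prior!r}")


class FamilyScoreCache:
    """LRU cache of (node, sorted parent tuple) -> log family score."""

    def __init__(self, max_size: int = 1_000_000) -> None:
        self._store: OrderedDict[tuple[int, tuple[int, ...]], float] = OrderedDict()
        self.max_size = max_size
        self.hits = 0
        self.misses = 0

    def get(self, node: int, parents: tuple[int, ...]) -> float | None:
        key = (node, parents)
        if key in self._store:
            self._store.move_to_end(key)
            self.hits += 1
            return self._store[key]
        self.misses += 1
        return None

    def put(self, node: int, parents: tuple[int, ...], value: float) -> None:
        self._store[(node, parents)] = value
        if len(self._store) > self.max_size:
            self._store.popitem(last=False)

    def __len__(self) -> int:
        return len(self._store)


def family_log_score(
    node: int,
    parent_set: tuple[int, ...],
    dataset: DiscreteDataset,
    cache: FamilyScoreCache | None = None,
) -> float:
    """K2 log family score of one node given its parent set.

    Zero observations (or parent configurations never observed) contribute
    nothing, so an empty dataset scores 0 for every family.
    """
    if node in parent_set:
        raise ValueError("node cannot be its own parent")
    parents = tuple(sorted(parent_set))
    if cache is not None:
        cached = cache.get(node, parents)
        if cached is not None:
            return cached
    matrix = dataset.matrix()
    arities = dataset.arity_vector()
    value = _family_log_score_counts(matrix, arities, node, parents)
    if cache is not None:
        cache.put(node, parents, value)
    return value


def _family_log_score_counts(
    matrix: np.ndarray, arities: np.ndarray, node: int, parents: tuple[int, ...]
) -> float:
    r = int(arities[node])
    n = matrix.shape[0]
    if n == 0:
        return 0.0
    if parents:
        # mixed-radix parent configuration index
        config = np.zeros(n, dtype=np.int64)
        q = 1
        for p in parents:
            config += matrix[:, p] * q
            q *= int(arities[p])
    else:
        config, q = np.zeros(n, dtype=np.int64), 1
    joint = config * r + matrix[:, node]
    counts = np.bincount(joint, minlength=q * r).reshape(q, r)
    n_j = counts.sum(axis=1)
    observed = n_j > 0
    lg_r = lgamma(r)
    total = float(np.sum(lg_r - gammaln(r + n_j[observed])))
    total += float(np.sum(gammaln(1 + counts[observed])))
    return total


def log_marginal_likelihood(
    structure: DAGStructure,
    dataset: DiscreteDataset,
    cache: FamilyScoreCache | None = None,
) -> float:
    """log P(D | G): sum of family scores over all nodes."""
    if structure.node_names != dataset.variable_names:
        raise ValueError("structure nodes do not match dataset variables")
    return sum(
        family_log_score(v, ps, dataset, cache)
        for v, ps in enumerate(structure.parent_sets)
    )


def log_structure_prior(structure: DAGStructure, config: ScoreConfig | None = None) -> float:
    """Log prior over structures.

    ``uniform_dags`` (default): constant (0) on the acyclic, in-degree
    bounded space, -inf outside — literally a uniform prior over allowed
    structures.  ``parent_set_size``: the cardinality-penalised alternative
    ``P(G) prop. prod_v 1 / C(n-1, |pa(v)|)``, still -inf outside the
    allowed space.
    """
    config = config or ScoreConfig()
    bound = config.max_in_degree
    if any(len(ps) > bound for ps in structure.parent_sets) or not is_acyclic(structure):
        return float("-inf")
    if config.structure_prior == "uniform_dags":
        return 0.0
    n = structure.n_nodes
    return -float(
        sum(np.log(binom(n - 1, len(ps))) for ps in structure.parent_sets)
    )
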