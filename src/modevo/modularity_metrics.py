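"""Modularity quantification of evolved input-to-hidden connection masks.

The I x H boolean mask is symmetrized into a bipartite association matrix on
I + H nodes.  Modularity of a partition is scored two ways:

* **Newman-Girvan Q** — fraction of edges within groups minus the expectation
  under random placement with the same degree fractions (standard unipartite
  formula applied to the symmetrized matrix, matching the social-network
  workflow the simulations are analysed with);
* **faction cost** — missing within-group ties plus present between-group
  ties, the "separate clique-like structures" criterion; zero for a union of
  disconnected cliques partitioned as cliques.

The faction cost is minimized by a Tabu search over single-node group
reassignments (best-improvement scan, reverse moves tabu for a fixed tenure,
aspiration when a move beats the incumbent, several random starts).  For
graphs of up to 12 nodes an exhaustive set-partition oracle provides ground
truth for testing.  Degree-preserving nulls keep every input node's degree
but re-draw its hidden-layer targets uniformly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "AssociationMatrix",
    "Partition",
    "TabuParams",
    "association_matrix",
    "newman_q",
    "faction_cost",
    "tabu_factions",
    "girvan_newman_partition",
    "degree_preserving_null",
    "exhaustive_faction_oracle",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric (I+H) x (I+H) adjacency; inputs first, hidden nodes after."""

    adjacency: np.ndarray
    n_inputs: int
    n_hidden: int

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        n = self.n_inputs + self.n_hidden
        if a.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("association matrix must be symmetric")
        if np.diagonal(a).any():
            raise ValueError("association matrix must have a zero diagonal")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))

    @property
    def n_nodes(self) -> int:
        return self.n_inputs + self.n_hidden

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        roles = {
            i: ("input" if i < self.n_inputs else "hidden") for i in range(self.n_nodes)
        }
        nx.set_node_attributes(g, roles, "role")
        return g


@dataclass
class Partition:
    """Group assignment of association-matrix nodes, with its scores."""

    labels: np.ndarray
    n_groups: int
    faction_cost: int | None = None
    q: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d assignment")
        if self.labels.min() < 0 or self.labels.max() >= self.n_groups:
            raise ValueError("labels must lie in [0, n_groups)")
        if not 1 <= self.n_groups <= self.labels.size:
            raise ValueError("n_groups must lie in [1, node count]")


@dataclass(frozen=True)
class TabuParams:
    """Tabu-search controls: series length 20, tenure 15, 3 random starts."""

    max_iterations_per_series: int = 20
    tabu_tenure: int = 15
    random_starts: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.max_iterations_per_series, self.tabu_tenure, self.random_starts) <= 0:
            raise ValueError("all Tabu parameters must be positive")


def _adjacency(adj) -> np.ndarray:
    if isinstance(adj, AssociationMatrix):
        return adj.adjacency.astype(float)
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return a


def _labels(partition) -> np.ndarray:
    labels = partition.labels if isinstance(partition, Partition) else partition
    return np.asarray(labels, dtype=int)


def association_matrix(mask: np.ndarray) -> AssociationMatrix:
    """Symmetrize an I x H connection mask into a bipartite adjacency matrix."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-d I x H matrix")
    i, h = mask.shape
    a = np.zeros((i + h, i + h), dtype=np.uint8)
    a[:i, i:] = mask
    a[i:, :i] = mask.T
    return AssociationMatrix(a, i, h)


def newman_q(adj, partition) -> float:
    """Newman-Girvan modularity Q = sum_g (e_gg - a_g^2) in [-1, 1].

    ``e_gh`` is the fraction of edges joining groups g and h and ``a_g`` the
    fraction of edge ends in g.  A graph with no edges scores 0 by convention.
    """
    a = _adjacency(adj)
    labels = _labels(partition)
    if labels.size != a.shape[0]:
        raise ValueError("partition must cover every node")
    total = a.sum()
    if total == 0:
        return 0.0
    k = labels.max() + 1
    onehot = np.eye(k)[labels]
    e = onehot.T @ a @ onehot / total
    return float(np.trace(e) - (e.sum(axis=1) ** 2).sum())


def faction_cost(adj, partition) -> int:
    """Missing within-group ties plus present between-group ties."""
    a = _adjacency(adj)
    labels = _labels(partition)
    if labels.size != a.shape[0]:
        raise ValueError("partition must cover every node")
    k = labels.max() + 1
    onehot = np.eye(k)[labels]
    sizes = onehot.sum(axis=0)
    within_pairs = (sizes * (sizes - 1) / 2).sum()
    within_edges = np.trace(onehot.T @ a @ onehot) / 2
    total_edges = a.sum() / 2
    missing_within = within_pairs - within_edges
    between_present = total_edges - within_edges
    return int(round(missing_within + between_present))


def _tabu_series(
    a: np.ndarray,
    n_groups: int,
    params: TabuParams,
    rng: np.random.Generator,
    incumbent_cost: float,
) -> tuple[np.ndarray, float]:
    """One Tabu series from a random initial partition; returns its best."""
    n = a.shape[0]
    labels = rng.integers(0, n_groups, n)
    counts = a @ np.eye(n_groups)[labels]  # neighbours of each node per group
    sizes = np.bincount(labels, minlength=n_groups).astype(float)
    cost = float(faction_cost(a, Partition(labels, n_groups)))
    best_labels, best_cost = labels.copy(), cost
    tabu_until = np.full((n, n_groups), -1, dtype=int)
    node_idx = np.arange(n)
    iteration = 0
    non_improving = 0
    while non_improving < params.max_iterations_per_series:
        iteration += 1
        k_self = counts[node_idx, labels]
        # cost change of moving node v from its group a to group b:
        # s_b - 2 k_b(v) - s_a + 1 + 2 k_a(v)
        delta = sizes[None, :] - 2 * counts + (2 * k_self - sizes[labels] + 1)[:, None]
        delta[node_idx, labels] = np.inf
        forbidden = tabu_until >= iteration
        aspiring = cost + delta < min(best_cost, incumbent_cost)
        allowed = np.where(forbidden & ~aspiring, np.inf, delta)
        if not np.isfinite(allowed).any():
            allowed = delta  # everything tabu and nothing aspiring: ignore tenure
        v, b = np.unravel_index(np.argmin(allowed), allowed.shape)
        old = labels[v]
        cost += delta[v, b]
        counts[:, old] -= a[:, v]
        counts[:, b] += a[:, v]
        sizes[old] -= 1
        sizes[b] += 1
        labels[v] = b
        tabu_until[v, old] = iteration + params.tabu_tenure
        if cost < best_cost - 1e-9:
            best_labels, best_cost = labels.copy(), cost
            non_improving = 0
        else:
            non_improving += 1
    return best_labels, best_cost


def tabu_factions(adj, n_groups: int, params: TabuParams | None = None) -> Partition:
    """Minimize the faction cost by Tabu search; deterministic given the seed.

    Runs ``params.random_starts`` independent series, each from a fresh random
    initial partition (its own sub-seed), and returns the lowest-cost
    partition found with its faction cost and Q attached.
    """
    params = params or TabuParams()
    a = _adjacency(adj)
    n = a.shape[0]
    if n_groups < 2:
        raise ValueError("n_groups must be at least 2")
    if n_groups > n:
        raise ValueError(f"n_groups = {n_groups} exceeds node count {n}")
    best_labels, best_cost = None, np.inf
    for start_ss in np.random.SeedSequence(params.seed).spawn(params.random_starts):
        labels, cost = _tabu_series(
            a, n_groups, params, np.random.default_rng(start_ss), best_cost
        )
        if cost < best_cost:
            best_labels, best_cost = labels, cost
    return Partition(
        best_labels,
        n_groups,
        faction_cost=int(round(best_cost)),
        q=newman_q(a, best_labels),
    )


def girvan_newman_partition(adj, n_groups: int | None = None) -> Partition:
    """Divisive edge-betweenness community detection.

    Iteratively removes the highest-betweenness edge; among the nested
    component structures returns the one maximizing Q, or the first with at
    least ``n_groups`` components when that is given (the pre-removal
    component structure counts as the first candidate, so already-disconnected
    graphs are handled).
    """
    a = _adjacency(adj)
    g = nx.from_numpy_array(a)
    n = a.shape[0]

    def as_labels(communities) -> np.ndarray:
        labels = np.empty(n, dtype=int)
        for gi, nodes in enumerate(communities):
            labels[list(nodes)] = gi
        return labels

    initial = [sorted(c) for c in nx.connected_components(g)]
    candidates: list[np.ndarray] = [as_labels(initial)]
    if g.number_of_edges() > 0:
        for communities in nx.algorithms.community.girvan_newman(g):
            candidates.append(as_labels(communities))
            if n_groups is not None and len(communities) >= n_groups:
                break
    if n_groups is not None:
        for labels in candidates:
            if labels.max() + 1 >= n_groups:
                chosen = labels
                break
        else:
            chosen = candidates[-1]
    else:
        chosen = max(candidates, key=lambda lab: newman_q(a, lab))
    k = int(chosen.max()) + 1
    return Partition(
        chosen, k, faction_cost=faction_cost(a, chosen), q=newman_q(a, chosen)
    )


def degree_preserving_null(
    mask: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Re-draw each input node's hidden targets uniformly, preserving its degree."""
    mask = np.asarray(mask, dtype=bool)
    i, h = mask.shape
    degrees = mask.sum(axis=1)
    if (degrees > h).any():
        raise ValueError("input degree exceeds hidden-layer size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.zeros_like(mask)
    for row, d in enumerate(degrees):
        if d:
            null[row, rng.choice(h, size=d, replace=False)] = True
    return null


def _set_partitions_upto(n: int, k: int) -> Iterator[np.ndarray]:
    """All set partitions of n items into at most k non-empty groups."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_used: int):
        if i == n:
            yield labels.copy()
            return
        for g in range(min(max_used + 1, k - 1) + 1):
            labels[i] = g
            yield from rec(i + 1, max(max_used, g))

    yield from rec(1, 0) if n > 1 else iter([labels.copy()])


def exhaustive_faction_oracle(adj, n_groups: int) -> Partition:
    """Ground-truth minimum faction cost by enumerating all set partitions.

    Limited to 12 nodes; intended as an independent oracle for
    :func:`tabu_factions` in tests, not for production-size graphs.
    """
    a = _adjacency(adj)
    n = a.shape[0]
    if n > 12:
        raise ValueError("exhaustive oracle is limited to 12 nodes")
    if not 1 <= n_groups <= n:
        raise ValueError("n_groups must lie in [1, node count]")
    best_labels, best_cost = None, np.inf
    for labels in _set_partitions_upto(n, n_groups):
        cost = faction_cost(a, Partition(labels, int(labels.max()) + 1))
        if cost < best_cost:
            best_labels, best_cost = labels, cost
    return Partition(
        best_labels,
        int(best_labels.max()) + 1,
        faction_cost=int(best_cost),
        q=newman_q(a, best_labels),
    )
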