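"""Shortest Hamiltonian path through cluster centroids.

Ordering k cluster centroids along a linear trajectory amounts to finding
the shortest Hamiltonian path in the complete graph whose vertices are the
centroids and whose edge weights are the Euclidean distances between them.
Equivalently it is a degree-constrained (max degree 2) minimum spanning
tree.  The problem is NP-hard, so the production solver is a greedy variant
of Kruskal's algorithm: edges are admitted in non-decreasing weight order,
skipping any edge that would close a cycle or raise a vertex degree above
two.  An exact exhaustive solver is provided for small instances so the
greedy heuristic can be validated against the true optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .errors import InternalConsistencyError, InvalidInputError, SizeError

__all__ = [
    "HamiltonianPath",
    "greedy_shortest_hamiltonian_path",
    "brute_force_shortest_hamiltonian_path",
    "path_length",
]

_BRUTE_FORCE_MAX_K = 10


@dataclass(frozen=True)
class HamiltonianPath:
    """A path visiting every vertex exactly once.

    Attributes
    ----------
    order
        Vertex indices in path order; a permutation of ``0..k-1`` in the
        canonical orientation (first endpoint index < last endpoint index,
        except for trivial k=1).
    length
        Sum of edge weights along consecutive pairs of ``order``.
    """

    order: tuple[int, ...]
    length: float

    @property
    def k(self) -> int:
        return len(self.order)


def _validate_distance_matrix(D) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidInputError(f"distance matrix must be square, got shape {D.shape}")
    if D.shape[0] < 2:
        raise InvalidInputError("distance matrix needs at least 2 vertices")
    if not np.all(np.isfinite(D)):
        raise InvalidInputError("distance matrix contains non-finite entries")
    if np.any(D < 0):
        raise InvalidInputError("distance matrix contains negative entries")
    if not np.allclose(D, D.T, rtol=0.0, atol=1e-12 * max(1.0, float(np.abs(D).max()))):
        raise InvalidInputError("distance matrix is not symmetric")
    if np.any(np.diagonal(D) != 0.0):
        raise InvalidInputError("distance matrix diagonal must be zero")
    return D


def _canonical(order: list[int]) -> tuple[int, ...]:
    if order[0] > order[-1]:
        order = order[::-1]
    return tuple(order)


def path_length(D, order) -> float:
    """Sum of distances over consecutive pairs of ``order``.

    Reversal-invariant; ``order`` may be a HamiltonianPath or any
    permutation of ``0..k-1``.
    """
    D = _validate_distance_matrix(D)
    if isinstance(order, HamiltonianPath):
        order = order.order
    idx = np.asarray(order, dtype=int)
    k = D.shape[0]
    if idx.shape != (k,) or not np.array_equal(np.sort(idx), np.arange(k)):
        raise InvalidInputError("order is not a permutation of 0..k-1")
    return float(D[idx[:-1], idx[1:]].sum())


def greedy_shortest_hamiltonian_path(D) -> HamiltonianPath:
    """Kruskal-style greedy heuristic for the shortest Hamiltonian path.

    Candidate edges are sorted by ``(weight, min index, max index)`` so
    equal-weight edges are admitted in a fixed order and the result is
    deterministic for a given matrix.  An edge is admitted unless it would
    create a cycle (union-find test) or give a vertex degree three.
    Exactly ``k - 1`` edges are admitted for any complete finite matrix.
    """
    D = _validate_distance_matrix(D)
    k = D.shape[0]
    iu, ju = np.triu_indices(k, 1)
    w = D[iu, ju]
    # stable sort on weight; iu/ju already in (min, max) lexicographic order
    edge_order = np.lexsort((ju, iu, w))

    parent = list(range(k))

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:  # path compression
            parent[a], a = root, parent[a]
        return root

    degree = [0] * k
    adj: list[list[int]] = [[] for _ in range(k)]
    n_edges = 0
    total = 0.0
    for e in edge_order:
        a, b = int(iu[e]), int(ju[e])
        if degree[a] >= 2 or degree[b] >= 2:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        degree[a] += 1
        degree[b] += 1
        adj[a].append(b)
        adj[b].append(a)
        total += float(w[e])
        n_edges += 1
        if n_edges == k - 1:
            break
    if n_edges != k - 1:
        raise InternalConsistencyError(
            f"greedy admitted {n_edges} edges, expected {k - 1}"
        )

    endpoints = [v for v in range(k) if degree[v] == 1]
    order = [min(endpoints)]
    prev = -1
    while len(order) < k:
        nxt = [v for v in adj[order[-1]] if v != prev]
        prev = order[-1]
        order.append(nxt[0])
    return HamiltonianPath(_canonical(order), total)


def brute_force_shortest_hamiltonian_path(D) -> HamiltonianPath:
    """Exact solver by exhaustive enumeration of all k!/2 undirected orders.

    Testing oracle only; refuses k > 10.  Ties between equally short paths
    are broken toward the lexicographically smallest canonical order.
    """
    D = _validate_distance_matrix(D)
    k = D.shape[0]
    if k > _BRUTE_FORCE_MAX_K:
        raise SizeError(f"brute force limited to k <= {_BRUTE_FORCE_MAX_K}, got {k}")
    best_order: tuple[int, ...] | None = None
    best_len = np.inf
    for perm in permutations(range(k)):
        if perm[0] > perm[-1]:  # each undirected path once, canonically
            continue
        idx = np.asarray(perm)
        length = float(D[idx[:-1], idx[1:]].sum())
        if length < best_len or (length == best_len and perm < best_order):
            best_len = length
            best_order = perm
    assert best_order is not None
    return HamiltonianPath(best_order, best_len)
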