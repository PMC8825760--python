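"""Discrete pseudotimes from path-permuted k-means clusterings.

A single k-means clustering carries ordering information once its arbitrary
labels are renamed to follow the shortest Hamiltonian path through the
cluster centroids: after renaming, consecutive integer labels are adjacent
clusters along the trajectory.  We call such a relabelled clustering a
discrete pseudotime.  Sweeping k over a range (default 2..100) yields an
ensemble of discrete pseudotimes, one column per k, which downstream
modules aggregate into a continuous pseudotime.

The Lloyd iteration here is deliberately written to be invariant to the
row order of the input: initial centroids are drawn from the
lexicographically sorted set of distinct rows, and all per-cluster sums are
accumulated in a canonical row order.  Permuting the cells therefore
permutes every discrete pseudotime exactly, which makes the whole pipeline
equivariant under cell shuffling.  Robustness of a single clustering is
intentionally low (one initialisation by default): the ensemble benefits
from dissimilar columns, which carry more information about relative cell
positions than many near-identical ones would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._seeds import derive_int_seed, derive_rng
from .errors import InfeasibleKError, InvalidInputError, InvalidParameterError
from .hampath import HamiltonianPath, greedy_shortest_hamiltonian_path

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterLabels",
    "PseudotimeSet",
    "kmeans_cluster",
    "centroid_distance_matrix",
    "relabel_to_discrete_pseudotime",
    "sweep_discrete_pseudotimes",
]

_MAX_LLOYD_ITER = 100


@dataclass(frozen=True)
class ClusterLabels:
    """A k-means partition: per-cell labels in 0..k-1 plus exact centroids.

    Centroids equal the mean of the member cells (recomputed after the
    final assignment, so the invariant holds even at the iteration cap).
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray


@dataclass(frozen=True)
class PseudotimeSet:
    """Cells x m matrix of discrete pseudotimes, one column per feasible k."""

    matrix: np.ndarray
    k_values: np.ndarray
    kmin: int
    kmax: int
    skipped_k: tuple[int, ...] = field(default=())

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self):
        """Export as a DataFrame with ``k=<v>`` column headers."""
        import pandas as pd

        return pd.DataFrame(
            self.matrix, columns=[f"k={v}" for v in self.k_values]
        )


def _validate_embedding(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise InvalidInputError(f"embedding must be 2-D, got {X.ndim}-D")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("embedding contains non-finite values")
    return X


def _canonical_order(X: np.ndarray) -> np.ndarray:
    """Lexicographic row order; invariant under row permutation of X."""
    return np.lexsort(X.T[::-1])


def _assign(X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    return d2.argmin(axis=1), d2


def _lloyd(
    X: np.ndarray, centroids: np.ndarray, canon: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    n, d = X.shape
    k = centroids.shape[0]
    Xc = X[canon]
    labels = np.full(n, -1, dtype=int)
    for _ in range(_MAX_LLOYD_ITER):
        new_labels, d2 = _assign(X, centroids)
        resid = d2[np.arange(n), new_labels]
        counts = np.bincount(new_labels, minlength=k)
        # empty-cluster repair: hand the farthest-from-centroid point over,
        # ties broken by canonical row order; re-scan because the donor
        # cluster may itself become empty
        empty = np.flatnonzero(counts == 0)
        while empty.size:
            j = int(empty[0])
            far = canon[np.argmax(resid[canon])]
            counts[new_labels[far]] -= 1
            new_labels[far] = j
            counts[j] += 1
            resid[far] = 0.0
            empty = np.flatnonzero(counts == 0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        # per-cluster sums in canonical order -> permutation-invariant floats
        sums = np.zeros((k, d))
        np.add.at(sums, labels[canon], Xc)
        centroids = sums / counts[:, None]
    sums = np.zeros((k, d))
    np.add.at(sums, labels[canon], Xc)
    counts = np.bincount(labels, minlength=k)
    centroids = sums / counts[:, None]
    _, d2 = _assign(X, centroids)
    wcss = float(d2[np.arange(n), labels][canon].sum())
    return labels, centroids, wcss


def kmeans_cluster(X, k: int, nstart: int = 1, seed: int = 0) -> ClusterLabels:
    """Lloyd's k-means with random data points as initial centroids.

    Run ``nstart`` times from independent random initialisations; the run
    with the lowest within-cluster sum of squares wins.  Initial centroids
    are sampled without replacement from the *distinct* rows, so every
    initial cluster is non-empty and the draw does not depend on the row
    order of ``X``.

    Raises
    ------
    InfeasibleKError
        If ``k`` exceeds the number of distinct rows (the sweep catches
        this and skips the k value).
    """
    X = _validate_embedding(X)
    if k < 2:
        raise InvalidParameterError(f"k must be >= 2, got {k}")
    if nstart < 1:
        raise InvalidParameterError(f"nstart must be >= 1, got {nstart}")
    uniq = np.unique(X, axis=0)
    if k > uniq.shape[0]:
        raise InfeasibleKError(
            f"k={k} exceeds the {uniq.shape[0]} distinct rows available"
        )
    canon = _canonical_order(X)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for run in range(nstart):
        rng = derive_rng(seed, "kmeans", run)
        init = uniq[rng.choice(uniq.shape[0], size=k, replace=False)]
        labels, centroids, wcss = _lloyd(X, init, canon)
        if best is None or wcss < best[2]:
            best = (labels, centroids, wcss)
    labels, centroids, _ = best
    return ClusterLabels(labels=labels, k=k, centroids=centroids)


def centroid_distance_matrix(labels: ClusterLabels) -> np.ndarray:
    """Pairwise Euclidean distances between cluster centroids."""
    if labels.k < 2:
        raise InvalidInputError("need at least 2 clusters for a distance matrix")
    return squareform(pdist(labels.centroids))


def relabel_to_discrete_pseudotime(
    labels: ClusterLabels, path: HamiltonianPath
) -> np.ndarray:
    """Rename cluster labels so label order follows the centroid path.

    Cluster ``path.order[j]`` becomes label ``j``: the new label of a cell
    is the position of its old label within the path.
    """
    k = labels.k
    order = np.asarray(path.order if isinstance(path, HamiltonianPath) else path)
    if not np.array_equal(np.sort(order), np.arange(k)):
        raise InvalidInputError("path order is not a permutation of 0..k-1")
    lab = np.asarray(labels.labels)
    if lab.min() < 0 or lab.max() >= k:
        raise InvalidInputError("cluster labels outside 0..k-1")
    position = np.empty(k, dtype=int)
    position[order] = np.arange(k)
    return position[lab]


def sweep_discrete_pseudotimes(
    X, kmin: int = 2, kmax: int = 100, nstart: int = 1, seed: int = 0
) -> PseudotimeSet:
    """One discrete pseudotime per k in ``[kmin, kmax]``.

    For each k: cluster, compute the centroid distance matrix, solve the
    greedy shortest Hamiltonian path, relabel.  Values of k above the
    number of distinct rows are skipped (and recorded), so small datasets
    run unchanged with the default ``kmax=100``.  Each k draws its k-means
    randomness from an independent sub-seed of ``seed``.
    """
    X = _validate_embedding(X)
    if kmin < 2:
        raise InvalidParameterError(f"kmin must be >= 2, got {kmin}")
    if kmin > kmax:
        raise InvalidParameterError(f"kmin={kmin} exceeds kmax={kmax}")
    if X.shape[0] < 3:
        raise InvalidInputError("need at least 3 cells for a sweep")
    columns: list[np.ndarray] = []
    k_values: list[int] = []
    skipped: list[int] = []
    for k in range(kmin, kmax + 1):
        sub_seed = derive_int_seed(seed, "kmeans", k)
        try:
            cl = kmeans_cluster(X, k, nstart=nstart, seed=sub_seed)
        except InfeasibleKError:
            skipped.append(k)
            continue
        D = centroid_distance_matrix(cl)
        path = greedy_shortest_hamiltonian_path(D)
        columns.append(relabel_to_discrete_pseudotime(cl, path))
        k_values.append(k)
    if skipped:
        logger.warning(
            "skipped %d infeasible k values (> distinct points): %s..%s",
            len(skipped),
            skipped[0],
            skipped[-1],
        )
    if not columns:
        raise InvalidInputError("no feasible k in the requested range")
    return PseudotimeSet(
        matrix=np.column_stack(columns),
        k_values=np.asarray(k_values),
        kmin=kmin,
        kmax=kmax,
        skipped_k=tuple(skipped),
    )
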