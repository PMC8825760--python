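"""Aggregate discrete pseudotimes into one crude continuous pseudotime.

The columns of a PseudotimeSet all attempt to order the same cells, but
each may run in either direction and some may be garbage (a bad clustering
or a badly permuted path).  PCA on the standardized columns sorts this
out: columns that share the dominant common ordering load heavily on the
first principal component, while columns orthogonal to it load on the
second.  We retain the columns whose PC1 loading magnitude exceeds their
PC2 loading magnitude — the largest mutually correlated subset — align
their directions using the loading signs, min-max scale each to [0, 1]
and average per cell.

``first_pc_pseudotime`` is the simpler alternative (use the PC1 scores
directly as the ensemble); it is kept both as the fallback when the
selection degenerates and for ablation comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .discrete import PseudotimeSet
from .errors import DegenerateInputError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "LoadingTable",
    "CrudePseudotime",
    "pca_loadings",
    "select_correlated",
    "aggregate",
    "first_pc_pseudotime",
]


@dataclass(frozen=True)
class LoadingTable:
    """First two PCA eigenvectors over the standardized pseudotime columns.

    ``columns`` maps entries back to PseudotimeSet column indices (columns
    with zero variance are dropped before standardization and do not
    appear).  Sign convention: each eigenvector is flipped so its
    largest-magnitude entry is positive, making results deterministic.
    """

    pc1_loadings: np.ndarray
    pc2_loadings: np.ndarray
    explained_variance: tuple[float, float]
    columns: np.ndarray
    _scores: np.ndarray | None = None  # cells x 2 PC scores, cached

    @property
    def pc1_sign(self) -> np.ndarray:
        return np.where(self.pc1_loadings >= 0, 1, -1)


@dataclass(frozen=True)
class CrudePseudotime:
    """Per-cell crude pseudotime in [0, 1] plus aggregation provenance."""

    values: np.ndarray
    n_selected: int
    selected_k: np.ndarray


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns to unit variance; returns (Z, kept-column mask)."""
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    return Z, keep


def _fix_sign(v: np.ndarray) -> np.ndarray:
    peak = np.argmax(np.abs(v))
    return -v if v[peak] < 0 else v


def pca_loadings(P: PseudotimeSet) -> LoadingTable:
    """Eigenvectors of the column correlation structure, via SVD.

    Columns are standardized (zero-variance columns dropped with a log
    message) and the first two right singular vectors returned with the
    deterministic sign convention above.
    """
    M = np.asarray(P.matrix, dtype=float)
    if M.shape[0] < 3:
        raise InvalidInputError("need at least 3 cells for PCA")
    Z, keep = _standardize(M)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance pseudotime columns before PCA", n_dropped)
    if Z.shape[1] < 2:
        raise DegenerateInputError(
            "fewer than 2 non-constant pseudotime columns; no correlation structure"
        )
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n = Z.shape[0]
    var = S**2 / (n - 1)
    v1, v2 = _fix_sign(Vt[0]), _fix_sign(Vt[1])
    scores = np.column_stack([Z @ v1, Z @ v2])
    return LoadingTable(
        pc1_loadings=v1,
        pc2_loadings=v2,
        explained_variance=(float(var[0]), float(var[1])),
        columns=np.flatnonzero(keep),
        _scores=scores,
    )


def select_correlated(L: LoadingTable) -> np.ndarray:
    """Columns contributing more to PC1 than PC2: ``|pc1| > |pc2|``.

    Returns PseudotimeSet column indices.  The caller applies the fallback
    (use PC1 scores directly) when fewer than 2 columns survive.
    """
    mask = np.abs(L.pc1_loadings) > np.abs(L.pc2_loadings)
    return L.columns[mask]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("cannot min-max scale a constant vector")
    return (x - lo) / (hi - lo)


def aggregate(
    P: PseudotimeSet, L: LoadingTable, selected: np.ndarray
) -> CrudePseudotime:
    """Scale, direction-align and average the selected columns.

    Each selected column is min-max scaled to [0, 1]; columns whose PC1
    loading is negative run against the majority direction and are flipped
    (x -> 1 - x); the per-cell mean over selected columns is the crude
    pseudotime.  Which global direction survives is arbitrary.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise InvalidInputError("empty column selection")
    col_to_pos = {int(c): i for i, c in enumerate(L.columns)}
    acc = np.zeros(P.n_cells)
    for c in selected:
        scaled = _minmax(P.matrix[:, c].astype(float))
        if L.pc1_loadings[col_to_pos[int(c)]] < 0:
            scaled = 1.0 - scaled
        acc += scaled
    values = acc / selected.size
    return CrudePseudotime(
        values=values,
        n_selected=int(selected.size),
        selected_k=np.asarray(P.k_values)[selected],
    )


def first_pc_pseudotime(P: PseudotimeSet) -> CrudePseudotime:
    """PC1 scores min-max scaled to [0, 1] — the direct aggregation mode."""
    L = pca_loadings(P)
    values = _minmax(L._scores[:, 0])
    return CrudePseudotime(
        values=values,
        n_selected=int(L.columns.size),
        selected_k=np.asarray(P.k_values)[L.columns],
    )
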