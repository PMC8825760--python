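"""End-to-end pipeline: dimensionality reduction, the four-step ensemble
pseudotime algorithm, and the direction flip helper.

The algorithm proper takes a low-dimensional embedding and composes:

1. a k-means sweep producing one path-permuted discrete pseudotime per k;
2. PCA over the standardized columns;
3. selection of the largest mutually correlated column subset by loading
   comparison (or the PC1 scores directly, as fallback or by request),
   followed by scaling, direction alignment and per-cell averaging;
4. LOESS smoothing of the crude average against its ranking, rescaled
   to [0, 1].

Expression matrices are first reduced with PCA and, by default, a 3-D
t-SNE (perplexity 30 on 50 principal components) — the common scRNA-seq
workflow.  ``dimred="none"`` passes coordinates through untouched so the
core algorithm is testable without a stochastic embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._seeds import derive_int_seed
from .discrete import (
    PseudotimeSet,
    _canonical_order,
    _validate_embedding,
    sweep_discrete_pseudotimes,
)
from .ensemble import (
    aggregate,
    first_pc_pseudotime,
    pca_loadings,
    select_correlated,
)
from .errors import InvalidInputError, InvalidParameterError
from .smoothing import LoessParams, smooth_pseudotime

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "reduce_dimensions",
    "infer_pseudotime",
    "flip_pseudotime",
]

_DIMRED_MODES = ("none", "pca", "pca_tsne")
_AGG_MODES = ("selection", "pc1")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables with their defaults.

    kmin/kmax bound the k-means sweep; nstart is the number of k-means
    initialisations per k (1 keeps columns dissimilar, which the ensemble
    exploits); span/degree parametrize the LOESS; n_pcs, perplexity and
    tsne_dims control preprocessing; aggregation picks the ensemble mode.
    """

    kmin: int = 2
    kmax: int = 100
    nstart: int = 1
    span: float = 0.1
    degree: int = 2
    n_pcs: int = 50
    perplexity: float = 30.0
    tsne_dims: int = 3
    dimred: str = "pca_tsne"
    aggregation: str = "selection"
    seed: int = 0

    def __post_init__(self):
        if self.kmin < 2:
            raise InvalidParameterError(f"kmin must be >= 2, got {self.kmin}")
        if not (0.0 < self.span <= 1.0):
            raise InvalidParameterError(f"span must be in (0, 1], got {self.span}")
        if self.dimred not in _DIMRED_MODES:
            raise InvalidParameterError(
                f"dimred must be one of {_DIMRED_MODES}, got {self.dimred!r}"
            )
        if self.aggregation not in _AGG_MODES:
            raise InvalidParameterError(
                f"aggregation must be one of {_AGG_MODES}, got {self.aggregation!r}"
            )


@dataclass(frozen=True)
class PipelineResult:
    """Continuous pseudotime in [0, 1] plus run provenance."""

    values: np.ndarray
    report: dict[str, Any]
    sweep: PseudotimeSet | None = field(default=None, repr=False)


def reduce_dimensions(E, cfg: PipelineConfig) -> np.ndarray:
    """Reduce an expression matrix to the embedding the algorithm orders.

    ``none`` returns the input unchanged, ``pca`` the top ``n_pcs``
    centered principal-component scores, ``pca_tsne`` additionally embeds
    the scores with t-SNE (seeded) into ``tsne_dims`` dimensions.
    """
    X = _validate_embedding(np.asarray(E, dtype=float))
    if cfg.dimred == "none":
        return X
    from sklearn.decomposition import PCA

    n, g = X.shape
    n_pcs = cfg.n_pcs
    limit = min(n, g) - 1
    if n_pcs > limit:
        logger.warning("n_pcs=%d truncated to %d (rank limit)", n_pcs, limit)
        n_pcs = limit
    if n_pcs < 1:
        raise InvalidInputError("matrix too small for PCA")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X)
    nonzero = pca.explained_variance_ > 1e-12
    if not np.all(nonzero):
        logger.warning(
            "dropping %d zero-variance components", int((~nonzero).sum())
        )
        scores = scores[:, nonzero]
    if cfg.dimred == "pca":
        return scores
    if n < 10:
        raise InvalidInputError("need at least 10 cells for t-SNE")
    if cfg.perplexity >= (n - 1) / 3:
        raise InvalidParameterError(
            f"perplexity {cfg.perplexity} too large for {n} cells "
            f"(must be < (cells-1)/3)"
        )
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=cfg.tsne_dims,
        perplexity=cfg.perplexity,
        random_state=derive_int_seed(cfg.seed, "tsne"),
        init="pca",
    )
    return tsne.fit_transform(scores)


def infer_pseudotime(
    X, cfg: PipelineConfig | None = None, *, _reuse_sweep: PseudotimeSet | None = None
) -> PipelineResult:
    """Run the four-step ensemble algorithm on an embedding.

    Returns the per-cell continuous pseudotime (direction arbitrary) and a
    report recording k values computed and skipped, the columns selected,
    and whether the PC1 fallback was triggered.  ``_reuse_sweep`` lets the
    aggregation ablation share one k-means sweep between modes.
    """
    cfg = cfg or PipelineConfig()
    X = _validate_embedding(X)
    if X.shape[0] < 3:
        raise InvalidInputError("need at least 3 cells")
    try:
        P = _reuse_sweep or sweep_discrete_pseudotimes(
            X, kmin=cfg.kmin, kmax=cfg.kmax, nstart=cfg.nstart, seed=cfg.seed
        )
    except Exception as exc:
        raise type(exc)(f"sweep stage: {exc}") from exc

    fallback = False
    try:
        if P.n_columns == 1:
            col = P.matrix[:, 0].astype(float)
            crude_values = (col - col.min()) / (col.max() - col.min())
            n_selected, selected_k = 1, [int(P.k_values[0])]
        elif cfg.aggregation == "pc1":
            crude = first_pc_pseudotime(P)
            crude_values = crude.values
            n_selected, selected_k = crude.n_selected, list(map(int, crude.selected_k))
        else:
            L = pca_loadings(P)
            selected = select_correlated(L)
            if selected.size < 2:
                logger.info(
                    "loading selection kept %d column(s); falling back to PC1 scores",
                    selected.size,
                )
                fallback = True
                crude = first_pc_pseudotime(P)
            else:
                crude = aggregate(P, L, selected)
            crude_values = crude.values
            n_selected, selected_k = crude.n_selected, list(map(int, crude.selected_k))
    except Exception as exc:
        raise type(exc)(f"ensemble stage: {exc}") from exc

    try:
        # canonical per-cell tie-break key keeps smoothing equivariant
        # under row permutation even when crude values tie exactly
        canon_rank = np.empty(X.shape[0])
        canon_rank[_canonical_order(X)] = np.arange(X.shape[0])
        values = smooth_pseudotime(
            crude_values,
            LoessParams(span=cfg.span, degree=cfg.degree),
            tie_key=canon_rank,
        )
    except Exception as exc:
        raise type(exc)(f"smoothing stage: {exc}") from exc

    report = {
        "n_cells": int(X.shape[0]),
        "k_values": [int(k) for k in P.k_values],
        "skipped_k": [int(k) for k in P.skipped_k],
        "n_selected": int(n_selected),
        "selected_k": selected_k,
        "fallback": fallback,
        "aggregation": cfg.aggregation,
        "span": cfg.span,
        "degree": cfg.degree,
        "seed": cfg.seed,
    }
    return PipelineResult(values=values, report=report, sweep=P)


def flip_pseudotime(p) -> np.ndarray:
    """Reverse trajectory direction: elementwise 1 - p (an involution)."""
    values = np.asarray(getattr(p, "values", p), dtype=float)
    return 1.0 - values
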