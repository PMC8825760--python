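"""File I/O: expression matrices in, pseudotimes out.

Supported inputs are dense CSV/TSV (rows = cells, first column the cell
id, header row the gene ids) and Matrix Market triplet files as written
by common 10x-style exporters (genes x cells, transposed on load, with
``barcodes.tsv`` / ``features.tsv`` sidecars next to the ``.mtx``).
Output is a two-column CSV ``cell_id,pseudotime`` at full float precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["ExpressionMatrix", "read_expression", "read_embedding", "write_pseudotime"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Cells x genes normalized expression with id sidecars."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        n, g = self.values.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise InvalidInputError(
                f"id lists ({len(self.cell_ids)} cells, {len(self.gene_ids)} genes) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.cell_ids)) != n:
            raise InvalidInputError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("expression matrix contains non-finite values")


def _read_dense(path: Path, sep: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise InvalidInputError(f"non-numeric entries in {path}")
    return ExpressionMatrix(
        values=values.astype(float),
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise InvalidInputError(f"missing sidecar file {path}")
    return [
        line.split("\t")[0].strip()
        for line in path.read_text().splitlines()
        if line.strip()
    ]


def _read_mtx(path: Path) -> ExpressionMatrix:
    try:
        mat = mmread(path)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    barcodes = _read_sidecar(path.parent / "barcodes.tsv")
    features = _read_sidecar(path.parent / "features.tsv")
    # Matrix Market convention: genes x cells -> transpose to cells x genes
    if values.shape != (len(features), len(barcodes)):
        raise InvalidInputError(
            f"matrix shape {values.shape} does not match "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(values=values.T, cell_ids=barcodes, gene_ids=features)


def read_expression(path, fmt: str = "csv") -> ExpressionMatrix:
    """Load an expression matrix; ``fmt`` is one of csv, tsv, mtx."""
    path = Path(path)
    if fmt == "csv":
        return _read_dense(path, ",")
    if fmt == "tsv":
        return _read_dense(path, "\t")
    if fmt == "mtx":
        return _read_mtx(path)
    raise InvalidParameterError(f"unknown format {fmt!r}; choose csv, tsv or mtx")


def read_embedding(path) -> tuple[np.ndarray, list[str]]:
    """Load a precomputed cells x dims embedding from CSV (cell id first)."""
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("embedding contains non-finite values")
    return values, [str(c) for c in df.index]


def write_pseudotime(p, cell_ids, path) -> None:
    """Write ``cell_id,pseudotime`` CSV in input cell order, full precision."""
    values = np.asarray(getattr(p, "values", p), dtype=float)
    if len(cell_ids) != values.size:
        raise InvalidInputError("cell_ids length does not match pseudotime length")
    pd.DataFrame({"cell_id": list(cell_ids), "pseudotime": values}).to_csv(
        path, index=False
    )
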