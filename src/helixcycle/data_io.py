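"""Reading, writing, normalizing and filtering genes × cells expression matrices.

The on-disk dialects supported are dense CSV/TSV (first column gene ids,
header row cell ids, optionally transposed) and MatrixMarket coordinate
format accompanied by two single-column name files. Phase-label files are
two-column TSV (cell_id, phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("helixcycle")

PHASES = ("G1", "S", "G2M")


class Scale(str, Enum):
    counts = "counts"
    fpkm = "fpkm"
    tpm = "tpm"
    log2 = "log2"


class ExpressionError(ValueError):
    """Structural or numerical problem with an expression matrix."""


@dataclass
class ExpressionMatrix:
    """A dense genes × cells expression matrix with identifiers.

    Attributes
    ----------
    values : ndarray, shape (D, N)
        Non-negative expression values (any scale but ``log2`` guarantees
        non-negativity too, since log2(x+1) >= 0 for x >= 0).
    gene_ids, cell_ids : list of str
        Unique row / column identifiers.
    scale : Scale
        What the numbers mean: raw ``counts``, ``fpkm``, ``tpm`` or
        ``log2``-transformed.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)
    scale: Scale = Scale.counts

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionError("expression values must be a 2-D matrix")
        d, n = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(d)]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{j}" for j in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.scale = Scale(self.scale)
        self.validate()

    def validate(self) -> None:
        d, n = self.values.shape
        if len(self.gene_ids) != d:
            raise ExpressionError(
                f"{len(self.gene_ids)} gene ids for {d} matrix rows"
            )
        if len(self.cell_ids) != n:
            raise ExpressionError(
                f"{len(self.cell_ids)} cell ids for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != d:
            raise ExpressionError("gene ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ExpressionError("cell ids are not unique")
        if not np.isfinite(self.values).all():
            raise ExpressionError("expression matrix contains NaN or Inf")
        if self.scale != Scale.log2 and (self.values < 0).any():
            raise ExpressionError(
                f"negative entries are not allowed on scale {self.scale.value!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.cell_ids), self.scale
        )


def _collapse_duplicate_genes(
    values: np.ndarray, gene_ids: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Sum rows sharing a gene id, keeping first-occurrence order."""
    if len(set(gene_ids)) == len(gene_ids):
        return values, gene_ids
    order: dict[str, int] = {}
    for g in gene_ids:
        if g not in order:
            order[g] = len(order)
    out = np.zeros((len(order), values.shape[1]))
    for row, g in zip(values, gene_ids):
        out[order[g]] += row
    n_dup = len(gene_ids) - len(order)
    logger.warning("collapsed %d duplicate gene id(s) by summing rows", n_dup)
    return out, list(order)


def read_expression(
    path: str | Path,
    format: str = "csv",
    orientation: str = "genes_by_cells",
    scale: Scale | str = Scale.counts,
    genes_file: str | Path | None = None,
    cells_file: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV, TSV or MatrixMarket.

    Parameters
    ----------
    path
        The matrix file. For ``mtx`` this is the coordinate file and
        `genes_file` / `cells_file` name its rows and columns (default:
        ``<path>.genes.txt`` / ``<path>.cells.txt`` next to it).
    format : {"csv", "tsv", "mtx"}
    orientation : {"genes_by_cells", "cells_by_genes"}
        How the file on disk is laid out; the returned matrix is always
        genes × cells.
    scale
        The scale to record on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except pd.errors.ParserError as exc:
            raise ExpressionError(f"malformed {format} file {path}: {exc}") from exc
        values = df.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    elif format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ExpressionError(f"malformed mtx file {path}: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        genes_file = Path(genes_file) if genes_file else path.with_suffix(".genes.txt")
        cells_file = Path(cells_file) if cells_file else path.with_suffix(".cells.txt")
        row_ids = genes_file.read_text().split()
        col_ids = cells_file.read_text().split()
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "cells_by_genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")

    if values.shape != (len(row_ids), len(col_ids)):
        raise ExpressionError(
            f"matrix is {values.shape} but name files give "
            f"{len(row_ids)} genes x {len(col_ids)} cells"
        )
    values, row_ids = _collapse_duplicate_genes(values, row_ids)
    return ExpressionMatrix(values, row_ids, col_ids, scale=scale)


def write_expression(
    m: ExpressionMatrix,
    path: str | Path,
    format: str = "csv",
    orientation: str = "genes_by_cells",
) -> None:
    """Write `m` in any of the dialects `read_expression` accepts."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
        if orientation == "cells_by_genes":
            df = df.T
        df.to_csv(path, sep=sep)
    elif format == "mtx":
        values = m.values.T if orientation == "cells_by_genes" else m.values
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(values))
        path.with_suffix(".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        path.with_suffix(".cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (cell_id, phase) into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "phase"],
                     dtype=str, comment="#")
    if df["cell_id"].duplicated().any():
        raise ExpressionError("duplicate cell ids in label file")
    return df.set_index("cell_id")["phase"]


def normalize_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform; refuses matrices that are already on log scale."""
    if m.scale == Scale.log2:
        raise ExpressionError("matrix is already log2-transformed")
    return ExpressionMatrix(
        np.log2(m.values + 1.0), list(m.gene_ids), list(m.cell_ids), Scale.log2
    )


def filter_genes(
    m: ExpressionMatrix,
    min_cell_fraction: float = 0.05,
    n_top: int | None = 2000,
) -> ExpressionMatrix:
    """Remove rarely expressed genes, then keep the most dispersed ones.

    A gene is dropped when it is expressed (value strictly greater than 0)
    in strictly fewer than ``min_cell_fraction * N`` cells. Among the
    survivors, the ``n_top`` genes with the highest dispersion
    (variance / mean of the *unlogged* values) are kept, preserving input
    gene order. ``n_top=None`` keeps all survivors.
    """
    if not 0 < min_cell_fraction < 1:
        raise ValueError("min_cell_fraction must be in (0, 1)")
    n = m.n_cells
    n_expressed = (m.values > 0).sum(axis=1)
    keep = n_expressed >= min_cell_fraction * n
    if not keep.any():
        raise ExpressionError(
            "all genes filtered out; lower min_cell_fraction or check the input"
        )
    idx = np.flatnonzero(keep)
    if n_top is not None and n_top < idx.size:
        if n_top < 1:
            raise ValueError("n_top must be >= 1")
        unlogged = m.values[idx]
        if m.scale == Scale.log2:
            unlogged = np.exp2(unlogged) - 1.0
        mean = unlogged.mean(axis=1)
        var = unlogged.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dispersion = np.where(mean > 0, var / mean, 0.0)
        top = np.argsort(-dispersion, kind="stable")[:n_top]
        idx = np.sort(idx[top])
    return ExpressionMatrix(
        m.values[idx],
        [m.gene_ids[i] for i in idx],
        list(m.cell_ids),
        m.scale,
    )
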