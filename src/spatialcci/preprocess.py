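"""Expression-matrix loading, filtering, standardization and noise injection.

The node features of the cell graph are a cells x genes expression matrix.
Cleaning follows the usual minimal recipe for graph-based CCI inference:
drop all-zero cells and genes, then z-score each gene. Controlled Gaussian
noise injection supports robustness benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class DegenerateInputError(ValueError):
    """Raised when filtering removes every cell or every gene."""


@dataclass
class ExpressionMatrix:
    """Dense cells x genes expression matrix with row/column labels.

    Parameters
    ----------
    values : (n_cells, n_genes) float array
        Expression values; must be finite.
    cell_ids, gene_ids : sequences of unique strings
        Row and column labels.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell labels for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"{len(self.gene_ids)} gene labels for {g} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids contain duplicates")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids contain duplicates")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def load_expression(path, fmt: str = "csv", transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV (cells x genes, labelled) or
    MatrixMarket with ``<stem>_cells.txt`` / ``<stem>_genes.txt`` sidecars.

    ``transpose=True`` flips a genes x cells file into the canonical
    cells x genes orientation (labels are swapped accordingly).
    """
    path = str(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
        cells, genes = list(df.index.astype(str)), list(df.columns.astype(str))
    elif fmt == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        values = np.asarray(mmread(path if path.endswith(".mtx") else path + ".mtx").todense(), dtype=float)
        with open(stem + "_cells.txt") as fh:
            cells = [line.strip() for line in fh if line.strip()]
        with open(stem + "_genes.txt") as fh:
            genes = [line.strip() for line in fh if line.strip()]
    else:
        raise ValueError(f"unknown format {fmt!r}; expected csv, tsv or mtx")

    if transpose:
        values = values.T
        cells, genes = genes, cells
    return ExpressionMatrix(values, cells, genes)


def save_expression(expr: ExpressionMatrix, path, fmt: str = "csv") -> None:
    path = str(path)
    if fmt in ("csv", "tsv"):
        expr.to_frame().to_csv(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "mtx":
        stem = path[:-4] if path.endswith(".mtx") else path
        mmwrite(stem + ".mtx", coo_matrix(expr.values))
        with open(stem + "_cells.txt", "w") as fh:
            fh.write("\n".join(expr.cell_ids) + "\n")
        with open(stem + "_genes.txt", "w") as fh:
            fh.write("\n".join(expr.gene_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def filter_all_zero(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop cells (rows) and genes (columns) whose entries are all zero.

    Raises :class:`DegenerateInputError` if nothing survives.
    """
    keep_cells = np.any(expr.values != 0, axis=1)
    keep_genes = np.any(expr.values != 0, axis=0)
    if not keep_cells.any() or not keep_genes.any():
        raise DegenerateInputError("filtering left zero cells or zero genes")
    values = expr.values[np.ix_(keep_cells, keep_genes)]
    return ExpressionMatrix(
        values,
        [c for c, k in zip(expr.cell_ids, keep_cells) if k],
        [g for g, k in zip(expr.gene_ids, keep_genes) if k],
    )


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene (population standard deviation).

    Zero-variance genes map to all-zero columns rather than raising, so that
    constant synthetic fixtures pass through.
    """
    mu = expr.values.mean(axis=0)
    sd = expr.values.std(axis=0)  # population (ddof=0)
    centered = expr.values - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(z, list(expr.cell_ids), list(expr.gene_ids))


def add_gaussian_noise(expr: ExpressionMatrix, std_dev: float, seed: int) -> ExpressionMatrix:
    """Add i.i.d. N(0, std_dev^2) noise to every entry. ``std_dev=0`` is the
    identity; the same seed always yields the same perturbation."""
    if std_dev < 0:
        raise ValueError(f"std_dev must be non-negative, got {std_dev}")
    if std_dev == 0:
        return ExpressionMatrix(expr.values.copy(), list(expr.cell_ids), list(expr.gene_ids))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, std_dev, size=expr.values.shape)
    return ExpressionMatrix(expr.values + noise, list(expr.cell_ids), list(expr.gene_ids))
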