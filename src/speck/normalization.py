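"""Library-size log-normalization of raw counts (Seurat dialect).

Each cell's counts are divided by that cell's total count, multiplied by a
scale factor (default 10 000), incremented by a pseudocount of one and
natural-log transformed:

    out[i, j] = ln(1 + counts[i, j] * scale_factor / total_i)

Zeros map to zeros, so the computation never densifies the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .matrix_io import CountMatrix

__all__ = ["ExpressionMatrix", "log_normalize"]


@dataclass
class ExpressionMatrix:
    """Log-normalized cells x genes expression (natural-log scale)."""

    values: sp.csr_matrix
    gene_symbols: list[str]
    cell_barcodes: list[str]
    scale_factor: float = 10_000.0

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Log-normalize a :class:`~speck.matrix_io.CountMatrix`.

    Raises
    ------
    ValueError
        If ``scale_factor`` is not positive or a cell has zero total count
        (the offending barcode is named).
    """
    if scale_factor <= 0:
        raise ValueError(f"scale_factor must be positive, got {scale_factor}")
    X = counts.values.tocsr().astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero_cells = np.flatnonzero(totals == 0)
    if zero_cells.size:
        bc = counts.cell_barcodes[zero_cells[0]]
        raise ValueError(f"cell {bc!r} has zero total count; cannot normalize")
    X = X.copy()
    # per-row scaling applied directly to the CSR data array
    row_of_entry = np.repeat(np.arange(X.shape[0]), np.diff(X.indptr))
    X.data *= scale_factor / totals[row_of_entry]
    np.log1p(X.data, out=X.data)
    return ExpressionMatrix(
        values=X,
        gene_symbols=list(counts.gene_symbols),
        cell_barcodes=list(counts.cell_barcodes),
        scale_factor=float(scale_factor),
    )
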