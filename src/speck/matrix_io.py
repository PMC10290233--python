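"""Readers and writers for cell x gene matrices in standard single-cell formats.

Two on-disk layouts are supported: the 10x Genomics Matrix Market convention
(``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, genes stored as rows)
and plain CSV with a header row of gene symbols and one cell per row.
Internally cells are always rows and genes are always columns; 10x input is
transposed at the boundary.  Gzipped files are accepted transparently.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "FeatureMap",
    "read_mtx",
    "read_csv",
    "write_matrix",
]


def _check_unique_symbols(symbols: Sequence[str]) -> None:
    """Reject gene symbols that collide after case-normalization."""
    lowered = [s.lower() for s in symbols]
    if len(set(lowered)) != len(lowered):
        seen: set[str] = set()
        dupes = sorted({s for s in lowered if s in seen or seen.add(s)})
        raise ValueError(
            f"duplicate gene symbols after case-normalization: {dupes[:5]}"
        )


@dataclass
class CountMatrix:
    """Raw cells x genes non-negative integer counts.

    Parameters
    ----------
    values
        Sparse or dense matrix of shape ``(n_cells, n_genes)`` holding
        non-negative integer counts.  Stored internally as CSR int64.
    gene_symbols
        One symbol per gene column.  Must be unique case-insensitively.
    cell_barcodes
        One barcode per cell row.
    """

    values: sp.csr_matrix
    gene_symbols: list[str]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        X = self.values
        if not sp.issparse(X):
            X = sp.csr_matrix(np.asarray(X))
        X = X.tocsr()
        if X.shape[0] == 0:
            raise ValueError("no cells")
        if X.shape[1] == 0:
            raise ValueError("no genes")
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError(
                f"need at least 2 cells and 2 genes, got {X.shape[0]} x {X.shape[1]}"
            )
        if X.nnz and X.data.min() < 0:
            raise ValueError("negative count in matrix")
        if not np.issubdtype(X.dtype, np.integer):
            if X.nnz and not np.allclose(X.data, np.round(X.data)):
                raise ValueError("non-integer count in matrix")
            X = X.astype(np.int64)
        else:
            X = X.astype(np.int64)
        X.eliminate_zeros()
        self.values = X
        self.gene_symbols = [str(s) for s in self.gene_symbols]
        self.cell_barcodes = [str(b) for b in self.cell_barcodes]
        if len(self.gene_symbols) != X.shape[1]:
            raise ValueError(
                f"{len(self.gene_symbols)} gene symbols for {X.shape[1]} gene columns"
            )
        if len(self.cell_barcodes) != X.shape[0]:
            raise ValueError(
                f"{len(self.cell_barcodes)} barcodes for {X.shape[0]} cell rows"
            )
        _check_unique_symbols(self.gene_symbols)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class FeatureMap:
    """Mapping from antibody names to gene symbols.

    Antibodies that map to more than one distinct gene symbol are ambiguous
    and are dropped (recorded in :attr:`dropped`), mirroring the standard
    practice of excluding antibodies without a unique HGNC symbol.
    """

    pairs: dict[str, str]
    dropped: tuple[str, ...] = field(default_factory=tuple)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "FeatureMap":
        by_ab: dict[str, set[str]] = {}
        for ab, sym in pairs:
            by_ab.setdefault(str(ab), set()).add(str(sym))
        kept = {ab: next(iter(syms)) for ab, syms in by_ab.items() if len(syms) == 1}
        dropped = tuple(sorted(ab for ab, syms in by_ab.items() if len(syms) > 1))
        if dropped:
            logger.info("dropped %d ambiguous antibodies: %s", len(dropped), dropped)
        return cls(pairs=kept, dropped=dropped)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "FeatureMap":
        """Read a two-column antibody<TAB>gene_symbol file (no header)."""
        rows: list[tuple[str, str]] = []
        with _open_text(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"expected 2 tab-separated columns in {path!s}")
                rows.append((parts[0], parts[1]))
        return cls.from_pairs(rows)

    def __len__(self) -> int:
        return len(self.pairs)


def _open_text(path: str | os.PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(dir_path: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            cand = dir_path / name
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {list(stems)} (or .gz variants) found in {dir_path}"
    )


def read_mtx(dir_path: str | os.PathLike) -> CountMatrix:
    """Load a 10x-style directory (matrix.mtx + features/genes + barcodes).

    On disk the matrix is genes x cells; the returned :class:`CountMatrix`
    is cells x genes.  The features file may have 2 columns
    (ensembl_id, symbol) or 3 (ensembl_id, symbol, feature_type); the
    symbol column is used.
    """
    dir_path = Path(dir_path)
    mtx_file = _find_file(dir_path, ["matrix.mtx"])
    feat_file = _find_file(dir_path, ["features.tsv", "genes.tsv"])
    bc_file = _find_file(dir_path, ["barcodes.tsv"])

    with _open_text(mtx_file) as fh:
        M = mmread(fh)  # genes x cells on disk
    M = sp.coo_matrix(M)
    if M.shape[0] == 0 or M.shape[1] == 0:
        raise ValueError("no cells")
    if M.nnz and M.data.min() < 0:
        raise ValueError("negative count in matrix file")

    features: list[str] = []
    with _open_text(feat_file) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            # 1-column files carry the symbol directly; 2/3-column 10x files
            # carry (ensembl, symbol[, type])
            features.append(parts[1] if len(parts) >= 2 else parts[0])
    with _open_text(bc_file) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if M.shape[0] != len(features):
        raise ValueError(
            f"matrix has {M.shape[0]} gene rows but features file has {len(features)}"
        )
    if M.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {M.shape[1]} cell columns but barcodes file has {len(barcodes)}"
        )
    return CountMatrix(
        values=M.T.tocsr(), gene_symbols=features, cell_barcodes=barcodes
    )


def read_csv(path: str | os.PathLike) -> CountMatrix:
    """Load a dense CSV: header row of gene symbols, first column barcodes."""
    values, genes, barcodes = read_dense_csv(path)
    return CountMatrix(
        values=sp.csr_matrix(values), gene_symbols=genes, cell_barcodes=barcodes
    )


def read_dense_csv(path: str | os.PathLike) -> tuple[np.ndarray, list[str], list[str]]:
    """Load any numeric cells x genes CSV; returns (values, genes, barcodes)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError("no gene columns")
    _check_unique_symbols([str(c) for c in df.columns])
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric entries in CSV")
    return values, [str(c) for c in df.columns], [str(i) for i in df.index]


def write_matrix(matrix, path: str | os.PathLike, format: str = "csv") -> None:
    """Write a matrix-like object (values/gene_symbols/cell_barcodes) to disk.

    ``format='csv'`` writes a single file; ``format='mtx'`` writes a 10x-style
    directory (matrix.mtx genes x cells, features.tsv, barcodes.tsv) in which
    zeros are not materialized.
    """
    path = Path(path)
    values = matrix.values
    genes = matrix.gene_symbols
    barcodes = matrix.cell_barcodes
    if format == "csv":
        dense = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values)
        df = pd.DataFrame(dense, index=barcodes, columns=genes)
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path)
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        S = values.tocsc() if sp.issparse(values) else sp.csc_matrix(np.asarray(values))
        S.eliminate_zeros()
        mmwrite(str(path / "matrix.mtx"), S.T)  # genes x cells on disk
        with open(path / "features.tsv", "w") as fh:
            for g in genes:
                fh.write(f"{g}\t{g}\n")
        with open(path / "barcodes.tsv", "w") as fh:
            for b in barcodes:
                fh.write(f"{b}\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'csv'")
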