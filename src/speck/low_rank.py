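"""Truncated randomized SVD, heuristic rank selection and reconstruction.

The pipeline computes a rank-100 (or smaller, if the matrix is smaller)
randomized SVD of the non-centered log-normalized matrix, derives the
standard deviations of the sample principal components
(``stdev_i = sigma_i / sqrt(m - 1)``), and scans the absolute consecutive
differences of those standard deviations for a plateau: the differences are
rounded (default 2 decimals, matching the 0.01 granularity of the rule) and
run-length encoded; among runs with value >= ``delta`` and length >=
``min_run``, the run with the smallest value marks the elbow, and the target
rank is that run's first (1-based) position plus one.  The chosen rank then
truncates the factors for the reduced-rank reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd as _sk_randomized_svd

__all__ = [
    "SvdFactors",
    "RankSelection",
    "ReducedRankMatrix",
    "randomized_svd",
    "select_rank",
    "rank_from_stdevs",
    "reconstruct",
    "run_length_encode",
]


@dataclass
class SvdFactors:
    """Truncated SVD triple ``X ~ U diag(s) Vt`` of a cells x genes matrix."""

    left_vectors: np.ndarray  # (m, r)
    singular_values: np.ndarray  # (r,) non-increasing
    right_vectors: np.ndarray  # (n, r)
    r: int
    n_cells: int
    gene_symbols: list[str] | None = None
    cell_barcodes: list[str] | None = None


@dataclass
class RankSelection:
    """Diagnostics of the elbow heuristic on the PC standard deviations."""

    stdevs: np.ndarray
    rate_of_change: np.ndarray
    rounded_roc: np.ndarray
    runs: list[tuple[float, int]]
    selected_rank: int
    fallback: bool = False
    decimals: int = 2
    delta: float = 0.01
    min_run: int = 2

    def to_dict(self) -> dict:
        return {
            "stdevs": [float(v) for v in self.stdevs],
            "rounded_roc": [float(v) for v in self.rounded_roc],
            "runs": [[float(v), int(l)] for v, l in self.runs],
            "selected_rank": int(self.selected_rank),
            "fallback": bool(self.fallback),
        }


@dataclass
class ReducedRankMatrix:
    """Dense rank-k reconstruction of the expression matrix (may be negative)."""

    values: np.ndarray
    rank_used: int
    gene_symbols: list[str] | None = None
    cell_barcodes: list[str] | None = None


def _as_array(X):
    """Accept an ExpressionMatrix-like object, a sparse matrix or an ndarray."""
    values = getattr(X, "values", X)
    if sp.issparse(values):
        return values
    return np.asarray(values, dtype=np.float64)


def randomized_svd(X, max_rank: int = 100, seed: int | None = 42) -> SvdFactors:
    """Rank-``min(max_rank, m-1, n)`` randomized SVD of the non-centered matrix.

    Uses power iterations and oversampling so that on small matrices the
    result agrees with an exact dense SVD to high precision; with a fixed
    ``seed`` the output is bit-reproducible on one platform.
    """
    A = _as_array(X)
    m, n = A.shape
    if max_rank < 2:
        raise ValueError(f"max_rank must be >= 2, got {max_rank}")
    if m < 2 or n < 2:
        raise ValueError(f"matrix must be at least 2 x 2, got {m} x {n}")
    nrm = sp.linalg.norm(A) if sp.issparse(A) else np.linalg.norm(A)
    if nrm == 0:
        raise ValueError("all-zero matrix has no meaningful SVD rank")
    r = min(max_rank, m - 1, n)
    U, s, Vt = _sk_randomized_svd(
        A,
        n_components=r,
        n_oversamples=max(10, r // 10),
        n_iter=4,
        power_iteration_normalizer="QR",
        random_state=seed,
    )
    gene_symbols = getattr(X, "gene_symbols", None)
    cell_barcodes = getattr(X, "cell_barcodes", None)
    return SvdFactors(
        left_vectors=U,
        singular_values=s,
        right_vectors=Vt.T,
        r=r,
        n_cells=m,
        gene_symbols=gene_symbols,
        cell_barcodes=cell_barcodes,
    )


def run_length_encode(x: np.ndarray) -> list[tuple[float, int, int]]:
    """RLE of a 1D array: list of ``(value, length, start_index_0based)``."""
    x = np.asarray(x)
    if x.size == 0:
        return []
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [x.size]])
    return [(float(x[a]), int(b - a), int(a)) for a, b in zip(starts, ends)]


def rank_from_stdevs(
    stdevs: np.ndarray,
    delta: float = 0.01,
    min_run: int = 2,
    decimals: int = 2,
) -> RankSelection:
    """Apply the plateau rule to a sequence of PC standard deviations.

    Among runs of the rounded consecutive |differences| with value >= delta
    and length >= min_run, the run with the smallest value wins (earliest on
    ties) and the selected rank is its first 1-based position plus one.  If
    no run qualifies the full computed rank is used (with a warning); ranks
    below 2 are clamped to 2.
    """
    stdevs = np.asarray(stdevs, dtype=np.float64)
    r = stdevs.size
    if r < 3:
        raise ValueError(f"need at least 3 components to select a rank, got {r}")
    roc = np.abs(np.diff(stdevs))
    rounded = np.round(roc, decimals)
    runs3 = run_length_encode(rounded)
    qualifying = [t for t in runs3 if t[0] >= delta - 1e-12 and t[1] >= min_run]
    fallback = False
    if qualifying:
        best = min(qualifying, key=lambda t: (t[0], t[2]))
        # start index is 0-based; the rule counts 1-based, then adds one
        k = (best[2] + 1) + 1
    else:
        warnings.warn(
            f"no run of rounded |d stdev| >= {delta} with length >= {min_run}; "
            f"falling back to the full computed rank {r}",
            RuntimeWarning,
            stacklevel=2,
        )
        k = r
        fallback = True
    if k < 2:
        warnings.warn("selected rank below 2; clamped to 2", RuntimeWarning, stacklevel=2)
        k = 2
    return RankSelection(
        stdevs=stdevs,
        rate_of_change=roc,
        rounded_roc=rounded,
        runs=[(v, l) for v, l, _ in runs3],
        selected_rank=int(k),
        fallback=fallback,
        decimals=decimals,
        delta=delta,
        min_run=min_run,
    )


def select_rank(
    factors: SvdFactors,
    m: int | None = None,
    delta: float = 0.01,
    min_run: int = 2,
    decimals: int = 2,
) -> RankSelection:
    """Select the reconstruction rank from SVD factors of an m-cell matrix."""
    if m is None:
        m = factors.n_cells
    if m < 2:
        raise ValueError("need at least 2 cells for a standard deviation")
    stdevs = factors.singular_values / np.sqrt(m - 1)
    return rank_from_stdevs(stdevs, delta=delta, min_run=min_run, decimals=decimals)


def reconstruct(factors: SvdFactors, k: int) -> ReducedRankMatrix:
    """Dense rank-k product ``U[:, :k] diag(s[:k]) Vt[:k]``."""
    if not 1 <= k <= factors.r:
        raise ValueError(f"k must be in [1, {factors.r}], got {k}")
    U = factors.left_vectors[:, :k]
    s = factors.singular_values[:k]
    Vt = factors.right_vectors[:, :k].T
    values = (U * s) @ Vt
    return ReducedRankMatrix(
        values=values,
        rank_used=int(k),
        gene_symbols=factors.gene_symbols,
        cell_barcodes=factors.cell_barcodes,
    )
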