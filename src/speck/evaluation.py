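"""Benchmarking abundance estimates against CITE-seq ADT measurements.

ADT (antibody-derived tag) counts are a direct per-cell protein readout and
serve as ground truth.  They are compositional, so they are normalized with
a centered log-ratio transform, ``ln(1 + x / g)`` with
``g = exp(mean(ln(1 + x)))`` over the chosen margin (per cell across
antibodies by default).  Per-receptor agreement is quantified with rank
correlations (Spearman by default; Kendall tau-b and Pearson available),
and competing estimators are summarized by the proportion of receptors on
which each attains the highest correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .matrix_io import FeatureMap

logger = logging.getLogger(__name__)

__all__ = [
    "AdtMatrix",
    "CorrelationReport",
    "clr_normalize",
    "correlate",
    "proportion_best",
]

_STATS = {
    "spearman": lambda x, y: stats.spearmanr(x, y).statistic,
    "pearson": lambda x, y: stats.pearsonr(x, y).statistic,
    "kendall": lambda x, y: stats.kendalltau(x, y).statistic,  # tau-b
}


@dataclass
class AdtMatrix:
    """Cells x antibodies ADT matrix (raw counts or CLR-normalized)."""

    values: np.ndarray
    antibody_names: list[str]
    cell_barcodes: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        V = self.values
        if sp.issparse(V):
            V = np.asarray(V.todense())
        self.values = np.asarray(V, dtype=np.float64)
        if not self.normalized and self.values.size and self.values.min() < 0:
            raise ValueError("raw ADT counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class CorrelationReport:
    """Per-receptor correlations for one estimation method.

    ``correlations`` is indexed by receptor (gene symbol); undefined
    correlations (constant columns) are stored as NaN, i.e. missing.
    """

    method_name: str
    correlations: pd.Series
    stat_method: str = "spearman"
    n_cells: int = 0
    dropped_receptors: tuple[str, ...] = field(default_factory=tuple)


def clr_normalize(adt: AdtMatrix, margin: str = "cell") -> AdtMatrix:
    """Centered log-ratio transform of raw ADT counts.

    ``out = ln(1 + x / g)`` where ``g`` is the geometric mean of ``1 + x``
    over the margin: across antibodies within each cell (``margin='cell'``,
    default) or across cells within each antibody (``margin='feature'``).
    """
    if adt.normalized:
        raise ValueError("ADT matrix is already normalized")
    if margin not in ("cell", "feature"):
        raise ValueError(f"margin must be 'cell' or 'feature', got {margin!r}")
    X = adt.values
    axis = 1 if margin == "cell" else 0
    if np.any(X.sum(axis=axis) == 0):
        unit = "cell" if margin == "cell" else "antibody"
        raise ValueError(f"a {unit} has all-zero ADT counts; geometric mean undefined")
    g = np.exp(np.log1p(X).mean(axis=axis, keepdims=True))
    return AdtMatrix(
        values=np.log1p(X / g),
        antibody_names=list(adt.antibody_names),
        cell_barcodes=list(adt.cell_barcodes),
        normalized=True,
    )


def correlate(
    estimates,
    adt: AdtMatrix,
    feature_map: FeatureMap,
    method: str = "spearman",
    method_name: str | None = None,
) -> CorrelationReport:
    """Per-receptor correlation between estimate columns and ADT columns.

    ``estimates`` is any object with ``values`` (cells x genes),
    ``gene_symbols`` and ``cell_barcodes``.  Antibodies are matched to
    estimate genes through ``feature_map`` (case-insensitive); correlations
    are computed over the cells shared by both matrices.  Receptors whose
    estimate or ADT column is constant get NaN (missing), not zero.
    """
    if method not in _STATS:
        raise ValueError(f"method must be one of {sorted(_STATS)}, got {method!r}")
    if len(feature_map) == 0:
        raise ValueError("empty feature map")
    est_values = estimates.values
    if sp.issparse(est_values):
        est_values = np.asarray(est_values.todense())
    est_values = np.asarray(est_values, dtype=np.float64)
    gene_idx = {g.lower(): i for i, g in enumerate(estimates.gene_symbols)}
    ab_idx = {a: i for i, a in enumerate(adt.antibody_names)}

    est_bc = pd.Index(estimates.cell_barcodes)
    adt_bc = pd.Index(adt.cell_barcodes)
    shared = est_bc.intersection(adt_bc)
    if len(shared) == 0:
        raise ValueError("no overlapping cell barcodes between estimates and ADT")
    ei = est_bc.get_indexer(shared)
    ai = adt_bc.get_indexer(shared)

    stat = _STATS[method]
    values: dict[str, float] = {}
    dropped: list[str] = []
    for ab, sym in sorted(feature_map.pairs.items()):
        if ab not in ab_idx or sym.lower() not in gene_idx:
            dropped.append(ab)
            continue
        x = est_values[ei, gene_idx[sym.lower()]]
        y = adt.values[ai, ab_idx[ab]]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            values[sym] = np.nan
        else:
            values[sym] = float(stat(x, y))
    if dropped:
        logger.info("dropped %d unmatched antibodies: %s", len(dropped), dropped)
    if not values:
        raise ValueError("no antibody could be matched to an estimate gene")
    return CorrelationReport(
        method_name=method_name or "estimates",
        correlations=pd.Series(values, name=method).sort_index(),
        stat_method=method,
        n_cells=len(shared),
        dropped_receptors=tuple(dropped),
    )


def proportion_best(reports: dict[str, CorrelationReport] | list[CorrelationReport]) -> pd.Series:
    """Fraction of receptors on which each method has the highest correlation.

    Receptors missing (NaN) for any method are dropped (logged).  A receptor
    whose top correlation is tied among several methods is split fractionally
    across them, so the proportions always sum to 1.
    """
    if isinstance(reports, dict):
        named = {name: rep.correlations for name, rep in reports.items()}
    else:
        named = {rep.method_name: rep.correlations for rep in reports}
    if len(named) < 2:
        raise ValueError("need at least 2 methods to compare")
    table = pd.DataFrame(named)
    complete = table.dropna()
    n_dropped = len(table) - len(complete)
    if n_dropped:
        logger.info("dropped %d receptors with missing correlations", n_dropped)
    if complete.empty:
        raise ValueError("no receptor has a defined correlation for every method")
    wins = pd.Series(0.0, index=table.columns)
    for _, row in complete.iterrows():
        top = row.max()
        tied = row.index[row == top]
        wins[tied] += 1.0 / len(tied)
    return wins / len(complete)
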