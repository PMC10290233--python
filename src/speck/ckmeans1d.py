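"""Optimal univariate k-means clustering by dynamic programming.

Unlike Lloyd-style k-means, the 1D problem can be solved exactly: an optimal
partition into k clusters consists of k contiguous intervals of the sorted
values, and dynamic programming over interval costs finds the partition
minimizing the total within-cluster sum of squares (WCSS).  The result is
deterministic — there is no dependence on initial centers.

The implementation clusters the sorted *unique* values with multiplicities
as weights, which (a) guarantees that tied values are never split across a
cluster boundary and (b) shrinks the DP for tie-heavy inputs.  Interval
costs come from prefix sums of the (globally centered) values and their
squares, so each cost is O(1).

Cluster-number selection over a range uses a Gaussian-mixture BIC: each
cluster is modeled as a Gaussian with its own mean, variance and mixing
weight size/n; ``BIC = 2 loglik - (3k - 1) ln(n)`` and the k maximizing it
wins (smallest k on ties).  Cluster variances are floored at ``(0.01 *
range)**2`` so that singleton or near-degenerate clusters cannot earn an
unbounded likelihood reward and split tight groups apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np

__all__ = ["Clustering1D", "ckmeans_fixed_k", "select_k"]


@dataclass
class Clustering1D:
    """Partition of a 1D value vector into k sorted-contiguous clusters.

    ``assignments`` are labels 1..k in original input order, ordered by
    ascending cluster center; ``wcss`` is the total within-cluster sum of
    squared deviations from the cluster means.
    """

    assignments: np.ndarray
    centers: np.ndarray
    sizes: np.ndarray
    wcss: float
    k: int


def _prepare(values) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    xs, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    return x, xs, counts.astype(np.float64), inverse


@numba.njit(fastmath=False)
def _dp_kernel(S, S2, W, kmax):  # pragma: no cover - exercised via _dp
    n = W.size - 1
    D = np.full((kmax, n), np.inf)
    B = np.zeros((kmax, n), dtype=np.int64)
    for i in range(n):
        cnt = W[i + 1] - W[0]
        sx = S[i + 1] - S[0]
        c = S2[i + 1] - S2[0] - sx * sx / cnt
        D[0, i] = c if c > 0.0 else 0.0
    for t in range(1, kmax):
        for i in range(t, n):
            best = np.inf
            bestj = t
            for j in range(t, i + 1):
                cnt = W[i + 1] - W[j]
                sx = S[i + 1] - S[j]
                c = S2[i + 1] - S2[j] - sx * sx / cnt
                if c < 0.0:
                    c = 0.0
                v = D[t - 1, j - 1] + c
                if v < best:  # strict: ties keep the smallest j
                    best = v
                    bestj = j
            D[t, i] = best
            B[t, i] = bestj
    return D, B


def _dp(xs: np.ndarray, w: np.ndarray, kmax: int) -> tuple[np.ndarray, np.ndarray]:
    """DP over sorted unique values with weights.

    Returns ``(D, B)`` where ``D[t, i]`` is the optimal weighted WCSS of
    clustering unique values ``0..i`` into ``t + 1`` clusters and ``B[t, i]``
    is the start index of the last cluster in that optimum.
    """
    mu = np.average(xs, weights=w)
    xc = xs - mu  # global centering stabilizes the prefix-sum cost
    S = np.concatenate([[0.0], np.cumsum(w * xc)])
    S2 = np.concatenate([[0.0], np.cumsum(w * xc * xc)])
    W = np.concatenate([[0.0], np.cumsum(w)])
    return _dp_kernel(S, S2, W, kmax)


def _backtrack(B: np.ndarray, n: int, k: int) -> list[tuple[int, int]]:
    """Inclusive (start, end) unique-value index ranges of the k clusters."""
    bounds: list[tuple[int, int]] = []
    i = n - 1
    for t in range(k - 1, 0, -1):
        j = int(B[t, i])
        bounds.append((j, i))
        i = j - 1
    bounds.append((0, i))
    bounds.reverse()
    return bounds


def _build_result(
    x: np.ndarray,
    xs: np.ndarray,
    w: np.ndarray,
    inverse: np.ndarray,
    bounds: list[tuple[int, int]],
    wcss: float,
) -> Clustering1D:
    k = len(bounds)
    labels_unique = np.empty(xs.size, dtype=np.int64)
    centers = np.empty(k)
    sizes = np.empty(k, dtype=np.int64)
    for c, (a, b) in enumerate(bounds):
        labels_unique[a : b + 1] = c + 1
        seg_w = w[a : b + 1]
        centers[c] = np.average(xs[a : b + 1], weights=seg_w)
        sizes[c] = int(seg_w.sum())
    return Clustering1D(
        assignments=labels_unique[inverse],
        centers=centers,
        sizes=sizes,
        wcss=float(wcss),
        k=k,
    )


def ckmeans_fixed_k(values, k: int) -> Clustering1D:
    """Globally optimal k-cluster partition of a 1D array (exact DP).

    Raises
    ------
    ValueError
        If the input is empty, ``k < 1``, or ``k`` exceeds the number of
        distinct values.
    """
    x, xs, w, inverse = _prepare(values)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > xs.size:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({xs.size})"
        )
    D, B = _dp(xs, w, k)
    bounds = _backtrack(B, xs.size, k)
    return _build_result(x, xs, w, inverse, bounds, D[k - 1, xs.size - 1])


def _bic(
    xs: np.ndarray,
    w: np.ndarray,
    bounds: list[tuple[int, int]],
    wcss_total: float,
    value_range: float,
) -> float:
    """Gaussian-mixture BIC of one candidate clustering (higher is better)."""
    n = w.sum()
    k = len(bounds)
    var_floor = max((value_range * 0.01) ** 2, np.finfo(np.float64).tiny)
    loglik = 0.0
    for a, b in bounds:
        seg_w = w[a : b + 1]
        nc = seg_w.sum()
        mean = np.average(xs[a : b + 1], weights=seg_w)
        ss = float(np.sum(seg_w * (xs[a : b + 1] - mean) ** 2))
        var = max(ss / nc, var_floor)
        loglik += (
            nc * np.log(nc / n)
            - 0.5 * nc * np.log(2 * np.pi * var)
            - ss / (2 * var)
        )
    return 2.0 * loglik - (3.0 * k - 1.0) * np.log(n)


def select_k(values, kmin: int = 1, kmax: int = 4) -> Clustering1D:
    """Cluster with the number of clusters chosen from ``[kmin, kmax]`` by BIC.

    ``kmax`` is clamped down to the number of distinct values (with a
    warning); constant input therefore always yields a single cluster.
    """
    x, xs, w, inverse = _prepare(values)
    if kmin < 1:
        raise ValueError(f"kmin must be >= 1, got {kmin}")
    if kmin > kmax:
        raise ValueError(f"kmin={kmin} > kmax={kmax}")
    n_distinct = xs.size
    if kmax > n_distinct:
        if n_distinct > 1:
            warnings.warn(
                f"kmax={kmax} clamped to {n_distinct} distinct values",
                RuntimeWarning,
                stacklevel=2,
            )
        kmax = n_distinct
    kmin = min(kmin, kmax)
    if kmax == 1:
        return _build_result(x, xs, w, inverse, [(0, n_distinct - 1)], 0.0
                             if n_distinct == 1 else _single_cluster_wcss(xs, w))

    D, B = _dp(xs, w, kmax)
    value_range = float(xs[-1] - xs[0])
    best: tuple[float, int] | None = None
    cached: dict[int, list[tuple[int, int]]] = {}
    for k in range(kmin, kmax + 1):
        bounds = _backtrack(B, n_distinct, k)
        cached[k] = bounds
        bic = _bic(xs, w, bounds, D[k - 1, n_distinct - 1], value_range)
        if best is None or bic > best[0] + 1e-12:
            best = (bic, k)
    k = best[1]
    return _build_result(x, xs, w, inverse, cached[k], D[k - 1, n_distinct - 1])


def _single_cluster_wcss(xs: np.ndarray, w: np.ndarray) -> float:
    mean = np.average(xs, weights=w)
    return float(np.sum(w * (xs - mean) ** 2))
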