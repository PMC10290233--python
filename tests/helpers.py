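"""Independent oracles used by the test suite.

These are deliberately naive (enumeration, dense linear algebra) and share
no code with the implementation they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_wcss(values, k: int) -> float:
    """Minimal WCSS over all partitions of the sorted values into k intervals."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    S = np.concatenate([[0.0], np.cumsum(x)])
    S2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg(a: int, b: int) -> float:  # cost of x[a:b]
        cnt = b - a
        sx = S[b] - S[a]
        return max(S2[b] - S2[a] - sx * sx / cnt, 0.0)

    best = np.inf
    for splits in combinations(range(1, n), k - 1):
        bounds = (0, *splits, n)
        cost = sum(seg(bounds[i], bounds[i + 1]) for i in range(k))
        if cost < best:
            best = cost
    return float(best)


def exact_svd(A: np.ndarray):
    """Full dense SVD oracle."""
    return np.linalg.svd(np.asarray(A, dtype=np.float64), full_matrices=False)


def eckart_young_error(s: np.ndarray, k: int) -> float:
    """Frobenius error of the best rank-k approximation from exact singular values."""
    return float(np.sqrt(np.sum(s[k:] ** 2)))
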