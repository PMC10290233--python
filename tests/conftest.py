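import numpy as np
import pytest

import speck

BENCHMARK_SEED = 42


@pytest.fixture(scope="session")
def benchmark():
    """Default-size synthetic joint scRNA-seq/ADT benchmark (2000 x 300)."""
    return speck.simulate_joint(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark):
    """Pipeline stages on the benchmark: expr, factors, selection, reconstruction, result."""
    counts, _, _ = benchmark
    expr = speck.log_normalize(counts)
    factors = speck.randomized_svd(expr, seed=BENCHMARK_SEED)
    selection = speck.select_rank(factors)
    rec = speck.reconstruct(factors, selection.selected_rank)
    result = speck.speck(counts, seed=BENCHMARK_SEED)
    return {
        "counts": counts,
        "expr": expr,
        "factors": factors,
        "selection": selection,
        "reconstruction": rec,
        "result": result,
    }


@pytest.fixture(scope="session")
def small_counts():
    """A small deterministic count matrix for fast unit tests."""
    rng = np.random.default_rng(7)
    values = rng.poisson(1.2, size=(30, 12))
    values[0] += 1  # guard against an all-zero cell
    return speck.CountMatrix(
        values=values,
        gene_symbols=[f"G{i}" for i in range(12)],
        cell_barcodes=[f"C{i}" for i in range(30)],
    )
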