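import numpy as np
import pandas as pd
import pytest

import speck
from speck.evaluation import AdtMatrix, CorrelationReport, clr_normalize, correlate, proportion_best
from speck.matrix_io import FeatureMap


def _adt(values, names=None, barcodes=None, normalized=False):
    values = np.asarray(values, dtype=float)
    return AdtMatrix(
        values=values,
        antibody_names=names or [f"ab{j}" for j in range(values.shape[1])],
        cell_barcodes=barcodes or [f"c{i}" for i in range(values.shape[0])],
        normalized=normalized,
    )


class _Est:
    def __init__(self, values, genes, barcodes):
        self.values = np.asarray(values, dtype=float)
        self.gene_symbols = genes
        self.cell_barcodes = barcodes


class TestClr:
    def test_worked_example(self):
        # cell (1, 4): g = exp((ln2 + ln5)/2) = sqrt(10)
        adt = clr_normalize(_adt([[1.0, 4.0], [2.0, 2.0]]))
        g = np.sqrt(10)
        assert adt.values[0, 0] == pytest.approx(np.log1p(1 / g), abs=1e-12)
        assert adt.values[0, 1] == pytest.approx(np.log1p(4 / g), abs=1e-12)
        assert adt.normalized

    def test_identical_entries_map_identically(self):
        adt = clr_normalize(_adt([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]]))
        assert np.ptp(adt.values[0]) == 0.0

    def test_all_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            clr_normalize(_adt([[0.0, 0.0], [1.0, 2.0]]))

    def test_already_normalized_rejected(self):
        with pytest.raises(ValueError, match="already"):
            clr_normalize(_adt([[1.0, 2.0]], normalized=True))

    def test_feature_margin(self):
        raw = np.array([[1.0, 10.0], [3.0, 20.0], [5.0, 40.0]])
        adt = clr_normalize(_adt(raw), margin="feature")
        g0 = np.exp(np.log1p(raw[:, 0]).mean())
        assert adt.values[1, 0] == pytest.approx(np.log1p(3 / g0), abs=1e-12)


class TestCorrelate:
    def _pair(self, x, y):
        est = _Est(np.array(x)[:, None], ["CD4"], [f"c{i}" for i in range(len(x))])
        adt = _adt(np.array(y, dtype=float)[:, None], names=["abCD4"], normalized=True)
        fmap = FeatureMap.from_pairs([("abCD4", "CD4")])
        return est, adt, fmap

    @pytest.mark.parametrize("method", ["spearman", "pearson", "kendall"])
    def test_identical_columns_give_one(self, method):
        est, adt, fmap = self._pair([1, 2, 3, 4], [1, 2, 3, 4])
        rep = correlate(est, adt, fmap, method=method)
        assert rep.correlations["CD4"] == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["spearman", "pearson", "kendall"])
    def test_negated_columns_give_minus_one(self, method):
        est, adt, fmap = self._pair([1, 2, 3, 4], [-1, -2, -3, -4])
        rep = correlate(est, adt, fmap, method=method)
        assert rep.correlations["CD4"] == pytest.approx(-1.0)

    def test_spearman_formula_example(self):
        # x=(1,2,3,4), y=(1,3,2,4): 1 - 6*2/(4*15) = 0.8
        est, adt, fmap = self._pair([1, 2, 3, 4], [1, 3, 2, 4])
        rep = correlate(est, adt, fmap, method="spearman")
        assert rep.correlations["CD4"] == pytest.approx(0.8, abs=1e-12)

    def test_constant_column_recorded_missing(self):
        est, adt, fmap = self._pair([2, 2, 2, 2], [1, 3, 2, 4])
        rep = correlate(est, adt, fmap)
        assert np.isnan(rep.correlations["CD4"])

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = x + rng.normal(0, 0.5, size=50)
        for method in ("spearman", "kendall"):
            est1, adt1, fmap = self._pair(x, y)
            est2, adt2, _ = self._pair(np.exp(x), y)
            r1 = correlate(est1, adt1, fmap, method=method).correlations["CD4"]
            r2 = correlate(est2, adt2, fmap, method=method).correlations["CD4"]
            assert r1 == pytest.approx(r2, abs=1e-12)

    def test_case_insensitive_gene_match_and_cell_alignment(self):
        est = _Est([[1.0], [2.0], [3.0]], ["Cd4"], ["a", "b", "c"])
        adt = _adt([[3.0], [2.0], [1.0]], names=["abCD4"], barcodes=["c", "b", "a"], normalized=True)
        rep = correlate(est, adt, FeatureMap.from_pairs([("abCD4", "CD4")]))
        assert rep.correlations["CD4"] == pytest.approx(1.0)
        assert rep.n_cells == 3

    def test_errors(self):
        est, adt, fmap = self._pair([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="empty"):
            correlate(est, adt, FeatureMap(pairs={}))
        adt_disjoint = _adt([[1.0], [2.0], [3.0]], names=["abCD4"], barcodes=["x", "y", "z"], normalized=True)
        with pytest.raises(ValueError, match="overlapping"):
            correlate(est, adt_disjoint, fmap)


def _report(name, **corrs):
    return CorrelationReport(method_name=name, correlations=pd.Series(corrs))


class TestProportionBest:
    def test_three_of_four_wins(self):
        a = _report("A", r1=0.9, r2=0.8, r3=0.7, r4=0.1)
        b = _report("B", r1=0.5, r2=0.4, r3=0.3, r4=0.6)
        props = proportion_best([a, b])
        assert props["A"] == pytest.approx(0.75)
        assert props["B"] == pytest.approx(0.25)

    def test_exact_tie_split_fractionally(self):
        a = _report("A", r1=0.5, r2=0.9)
        b = _report("B", r1=0.5, r2=0.1)
        props = proportion_best([a, b])
        assert props["A"] == pytest.approx(0.75)
        assert props["B"] == pytest.approx(0.25)
        assert props.sum() == pytest.approx(1.0)

    def test_single_receptor_three_methods(self):
        props = proportion_best(
            [_report("A", r1=0.3), _report("B", r1=0.7), _report("C", r1=0.5)]
        )
        assert props["B"] == 1.0
        assert props["A"] == props["C"] == 0.0

    def test_missing_receptors_dropped(self):
        a = _report("A", r1=0.9, r2=np.nan)
        b = _report("B", r1=0.5, r2=0.8)
        props = proportion_best([a, b])
        assert props["A"] == 1.0  # r2 dropped for both

    def test_fewer_than_two_methods_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            proportion_best([_report("A", r1=0.5)])
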