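"""The chi-square termination rule and the ChiMIC sweep."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from chimic import (
    CATALOG,
    ContingencyTable,
    OptimizerConfig,
    PairedSample,
    TerminationConfig,
    approx_max_mi,
    chi_square_test,
    chimic_mic,
    equipartition,
    independent_pair,
    sample_function,
)
from chimic.chimic import chimic_x_axis, flanking_table


class TestChiSquareTest:
    def test_five_five_antidiagonal_with_correction(self):
        res = chi_square_test(ContingencyTable([[0, 5], [5, 0]]))
        assert res.statistic == pytest.approx(6.4)
        assert res.df == 1 and res.corrected
        assert res.p_value == pytest.approx(0.0114, abs=5e-5)

    def test_exact_independence_gives_p_one(self):
        res = chi_square_test(ContingencyTable([[5, 5], [5, 5]]))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_ten_ten_antidiagonal_statistic(self):
        # 4 cells, each (|10-5| - 0.5)^2 / 5 = 4.05
        res = chi_square_test(ContingencyTable([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(16.2)

    def test_proportional_columns_always_give_zero(self, rng):
        rows = rng.integers(1, 20, size=5)
        table = ContingencyTable(np.stack([rows * 2, rows * 3], axis=1))
        assert chi_square_test(table).statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_row_margins_are_excluded(self):
        full = chi_square_test(ContingencyTable([[4, 1], [0, 0], [1, 4]]))
        dropped = chi_square_test(ContingencyTable([[4, 1], [1, 4]]))
        assert full.statistic == pytest.approx(dropped.statistic)
        assert full.df == dropped.df == 1

    def test_degenerate_tables_return_p_one(self):
        assert chi_square_test(ContingencyTable([[0, 0], [0, 0]])).p_value == 1.0
        assert chi_square_test(ContingencyTable([[3, 0], [4, 0]])).p_value == 1.0

    @pytest.mark.parametrize("correct", [True, False])
    def test_agrees_with_scipy_on_regular_tables(self, rng, correct):
        for _ in range(20):
            counts = rng.integers(1, 30, size=(int(rng.integers(2, 5)), 2))
            ours = chi_square_test(ContingencyTable(counts), correct=correct)
            ref = chi2_contingency(counts, correction=correct)
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-8)
            assert ours.df == ref.dof


class TestFlankingTable:
    def test_margins_sum_to_restricted_count(self):
        s = independent_pair(60, 2)
        ypart = equipartition(s.ys, 3)
        xpart = equipartition(s.xs, 4)
        cut = int(xpart.cuts[1])
        table = flanking_table(s, ypart, xpart, cut)
        edges = xpart.edges
        j = int(np.searchsorted(edges, cut))
        assert table.shape == (3, 2)
        assert table.total == edges[j + 1] - edges[j - 1]

    def test_unknown_cut_rejected(self):
        s = independent_pair(20, 0)
        with pytest.raises(ValueError):
            flanking_table(s, equipartition(s.ys, 2), equipartition(s.xs, 2), 3)


class TestChimicXAxis:
    def test_noiseless_linear_stops_at_two_bins(self):
        s = sample_function("linear", 1000)
        part, trace = chimic_x_axis(s, equipartition(s.ys, 2))
        assert part.bins == 2
        assert trace[-1] == pytest.approx(1.0, abs=1e-12)

    def test_identical_column_split_terminates_immediately(self):
        # two interleaved diagonal strips: every candidate split leaves
        # proportional flanking columns, so EP_1 already fails the test
        x = np.arange(40.0)
        y = np.tile([0.0, 1.0], 20) + x * 1e-4
        s = PairedSample(x, y)
        part, trace = chimic_x_axis(s, equipartition(s.ys, 2))
        assert part.bins == 1 and trace == []

    def test_first_endpoint_free_under_legacy_reading(self):
        x = np.arange(40.0)
        y = np.tile([0.0, 1.0], 20) + x * 1e-4
        s = PairedSample(x, y)
        cfg = TerminationConfig(test_first_endpoint=False)
        part, _ = chimic_x_axis(s, equipartition(s.ys, 2), cfg)
        assert part.bins == 2  # EP_1 accepted, EP_2 rejected with p = 1

    def test_accepted_cuts_never_exceed_candidates(self):
        s = independent_pair(100, 9)
        part, trace = chimic_x_axis(s, equipartition(s.ys, 2))
        assert part.bins - 1 == len(trace) <= s.n - 1


class TestChimicMic:
    def test_noiseless_catalog_all_reach_one(self):
        for name in CATALOG:
            s = sample_function(name, 500)
            assert chimic_mic(s).mic == pytest.approx(1.0, abs=1e-9), name

    def test_dominated_by_dp_baseline_entrywise(self, medium_samples):
        # greedy-visited grids are a subset of what the DP optimizes over
        for s in medium_samples:
            chi = chimic_mic(s)
            dp = approx_max_mi(s)
            for key, val in chi.matrix.items():
                ref = dp.matrix.entries.get(key)
                assert ref is not None, key
                assert val <= ref + 1e-9
            assert chi.mic <= dp.mic + 1e-9

    def test_symmetry_under_axis_swap(self):
        s = independent_pair(90, 21)
        assert chimic_mic(s).mic == pytest.approx(
            chimic_mic(s.swapped()).mic, abs=1e-12
        )

    def test_empty_matrix_reports_zero_mic(self):
        # heavily rejected search: tiny independent sample
        found_zero = False
        for seed in range(30):
            res = chimic_mic(independent_pair(30, seed))
            if len(res.matrix) == 0:
                assert res.mic == 0.0 and res.best_shape is None
                found_zero = True
        assert found_zero

    def test_rank_invariance_under_monotone_transforms(self):
        s = independent_pair(120, 4)
        t = PairedSample(np.exp(2 * s.xs), s.ys**3 + 5 * s.ys)
        for fn in (chimic_mic, approx_max_mi):
            assert fn(s).mic == pytest.approx(fn(t).mic, abs=1e-12)

    def test_b_cap_flag_widens_search(self):
        s = sample_function("sinusoidal", 200, 0.1, seed=3)
        capped = chimic_mic(s)
        free = chimic_mic(s, TerminationConfig(apply_b_cap=False))
        cells_free = max(l * r for (l, r) in free.matrix.entries)
        assert cells_free >= max(l * r for (l, r) in capped.matrix.entries)
        assert free.mic >= capped.mic - 1e-12
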