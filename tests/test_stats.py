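"""Contingency-table construction, ROR/PRR/chi-square and table inversion.

Expected values for the worked examples were computed independently by
direct evaluation of the closed-form definitions (hand arithmetic for the
small tables) before the implementation existed.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignals as pv
from pvsignals.stats import (
    ContingencyTable,
    Thresholds,
    build_tables,
    compute_chi2,
    compute_metrics,
    compute_prr,
    compute_ror,
    flag_signal,
    rank_signals,
    reconstruct_table,
)

cells = st.integers(min_value=1, max_value=1_000_000)


class TestBuildTables:
    def test_toy_pair_sets(self):
        cohort = {("r1", "X"), ("r1", "Y"), ("r2", "X")}
        background = {("r3", "X"), ("r3", "Z")}
        tables = build_tables(cohort, background)
        assert tables["X"] == ContingencyTable(a=2, b=1, c=1, d=1)

    def test_pt_absent_from_background_gets_zero_c(self):
        tables = build_tables({("r1", "X")}, {("r2", "Y")})
        assert tables["X"] == ContingencyTable(a=1, b=0, c=0, d=1)

    def test_pairs_are_deduplicated(self):
        tables = build_tables(
            [("r1", "X"), ("r1", "X"), ("r2", "X")], [("r3", "Y")]
        )
        assert tables["X"].a == 2

    def test_a_plus_b_constant_across_pts(self):
        cohort = [("r1", "X"), ("r1", "Y"), ("r2", "X"), ("r3", "Z")]
        tables = build_tables(cohort, [("r4", "X")])
        totals = {t.a + t.b for t in tables.values()}
        assert totals == {4}

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_tables([], [("r1", "X")])


class TestClosedForms:
    def test_symmetric_table_is_null(self):
        t = ContingencyTable(5, 5, 5, 5)
        ror, lo, hi = compute_ror(t)
        assert ror == 1.0 and lo < 1.0 < hi
        assert compute_prr(t) == 1.0
        assert compute_chi2(t) == 0.0

    def test_hand_worked_table(self):
        # a=10, b=90, c=100, d=9900: ROR = (10*9900)/(90*100) = 11
        # PRR = (10/100)/(100/10000) = 10
        # chi2 = (10*9900-90*100)^2 * 10100 / (100*10000*110*9990)
        t = ContingencyTable(10, 90, 100, 9900)
        ror, lo, hi = compute_ror(t)
        assert ror == pytest.approx(11.0, abs=1e-12)
        assert compute_prr(t) == pytest.approx(10.0, abs=1e-12)
        chi2_hand = (90_000**2 * 10_100) / (100 * 10_000 * 110 * 9_990)
        assert compute_chi2(t) == pytest.approx(chi2_hand, rel=1e-12)
        assert round(compute_chi2(t), 2) == 74.45
        # CI evaluated independently from the closed form
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert lo == pytest.approx(math.exp(math.log(11.0) - 1.96 * se), rel=1e-12)
        assert hi == pytest.approx(math.exp(math.log(11.0) + 1.96 * se), rel=1e-12)

    def test_zero_cell_is_undefined_not_infinite(self):
        t = ContingencyTable(3, 0, 5, 10)
        ror, lo, hi = compute_ror(t)
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)
        m = compute_metrics(t)
        assert not m.defined
        assert not (m.ror_method_pass or m.mhra_pass or m.combined_pass)

    def test_haldane_continuity_on_request(self):
        t = ContingencyTable(3, 0, 5, 10)
        ror, lo, hi = compute_ror(t, continuity=0.5)
        assert math.isfinite(ror) and ror > 0
        expected = (3.5 * 10.5) / (0.5 * 5.5)
        assert ror == pytest.approx(expected, rel=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_chi2_symmetry(self, a, b, c, d):
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(d, c, b, a)
        assert compute_chi2(t1) == pytest.approx(compute_chi2(t2), rel=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=st.integers(1, 1000), b=cells, c=cells, d=cells)
    def test_monotone_in_a(self, a, b, c, d):
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b, c, d)
        assert compute_ror(t2)[0] > compute_ror(t1)[0]
        assert compute_prr(t2) > compute_prr(t1)

    def test_ror_approaches_prr_for_rare_events(self):
        # with b >= 100 a and a/N fixed small, the two ratios converge
        t = ContingencyTable(50, 10_000, 500, 1_000_000)
        ror, _, _ = compute_ror(t)
        prr = compute_prr(t)
        assert abs(ror - prr) / prr < 0.01

    def test_statsmodels_cross_check(self):
        """Independent implementation route: statsmodels Table2x2."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2024)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 10_000, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            tab = sm.stats.Table2x2([[a, b], [c, d]], shift_zeros=False)
            ror, lo, hi = compute_ror(t, z=1.959963984540054)
            assert ror == pytest.approx(tab.oddsratio, rel=1e-10)
            sm_lo, sm_hi = tab.oddsratio_confint(0.05)
            assert lo == pytest.approx(sm_lo, rel=1e-9)
            assert hi == pytest.approx(sm_hi, rel=1e-9)
            assert compute_chi2(t) == pytest.approx(
                tab.test_nominal_association().statistic, rel=1e-10
            )


class TestFlags:
    def test_all_thresholds_met_inclusive(self):
        m = pv.SignalMetrics(ror=2.5, ci_low=1.01, ci_high=5.0, prr=2.0, chi2=4.0)
        out = flag_signal(3, m)
        assert out.ror_method_pass and out.mhra_pass and out.combined_pass

    def test_case_count_gate(self):
        m = pv.SignalMetrics(ror=500.0, ci_low=100.0, ci_high=900.0, prr=400.0, chi2=999.0)
        out = flag_signal(2, m)
        assert not (out.ror_method_pass or out.mhra_pass or out.combined_pass)

    def test_methods_disagree_and_rule(self):
        m = pv.SignalMetrics(ror=3.0, ci_low=0.99, ci_high=9.0, prr=3.0, chi2=10.0)
        out = flag_signal(5, m)
        assert not out.ror_method_pass and out.mhra_pass and not out.combined_pass
        out_or = flag_signal(5, m, Thresholds(combined_rule="or"))
        assert out_or.combined_pass

    def test_flag_monotone_in_a(self):
        # raising a (with b, c, d fixed) never turns a passing signal failing
        base = ContingencyTable(3, 50, 40, 5000)
        passing = compute_metrics(base).combined_pass
        for a in range(4, 40):
            now = compute_metrics(ContingencyTable(a, 50, 40, 5000)).combined_pass
            assert now >= passing
            passing = now


class TestRanking:
    def _sig(self, pt, a, ror):
        t = ContingencyTable(a, 100, 50, 10_000)
        m = pv.SignalMetrics(
            ror=ror, ci_low=1.5, ci_high=ror * 2, prr=ror, chi2=50.0,
            ror_method_pass=True, mhra_pass=True, combined_pass=True,
        )
        return pv.SignalResult(pt=pt, table=t, metrics=m)

    def test_orders_by_case_count_then_ror(self):
        sigs = [self._sig("A", 3, 10.0), self._sig("B", 5, 2.0), self._sig("C", 3, 5.0)]
        ranked = rank_signals(sigs, key="case_count")
        assert [s.pt for s in ranked] == ["B", "A", "C"]

    def test_orders_by_ror(self):
        sigs = [self._sig("A", 3, 10.0), self._sig("B", 5, 2.0)]
        ranked = rank_signals(sigs, key="ror")
        assert [s.pt for s in ranked] == ["A", "B"]

    def test_alphabetical_last_resort(self):
        sigs = [self._sig("Zeta", 3, 5.0), self._sig("Alpha", 3, 5.0)]
        assert [s.pt for s in rank_signals(sigs)] == ["Alpha", "Zeta"]

    def test_clamp_and_errors(self):
        sigs = [self._sig("A", 3, 10.0)]
        assert len(rank_signals(sigs, n=20)) == 1
        with pytest.raises(ValueError):
            rank_signals(sigs, n=0)

    def test_only_passing_ranked(self):
        failing = self._sig("F", 99, 99.0)
        failing = pv.SignalResult(
            pt="F",
            table=failing.table,
            metrics=pv.SignalMetrics(
                ror=99.0, ci_low=1.5, ci_high=200.0, prr=99.0, chi2=50.0
            ),
        )
        assert rank_signals([failing]) == []


class TestReconstruction:
    def test_recovers_forward_computed_table(self):
        table, residual = reconstruct_table(a=10, ror=11.0, prr=10.0, chi2=74.45)
        assert (table.b, table.c, table.d) == (90, 100, 9900)
        assert residual < 1e-6

    def test_no_association_row_is_underdetermined(self):
        with pytest.raises(ValueError, match="underdetermined"):
            reconstruct_table(a=5, ror=1.0, prr=1.0, chi2=0.0)

    def test_inconsistent_statistics_rejected(self):
        # chi-square wildly incompatible with the ratios
        with pytest.raises(ValueError, match="inconsistent"):
            reconstruct_table(a=10, ror=11.0, prr=10.0, chi2=900_000.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a = int(rng.integers(5, 200))
        b = int(rng.integers(a * 3, a * 50))
        c = int(rng.integers(50, 5000))
        d = int(rng.integers(c * 20, c * 200))
        t = ContingencyTable(a, b, c, d)
        ror = round(compute_ror(t)[0], 2)
        prr = round(compute_prr(t), 2)
        chi2 = round(compute_chi2(t), 2)
        if abs(ror - prr) <= 0.01 or prr <= 1.005:
            pytest.skip("degenerate draw: statistics not invertible")
        rec, residual = reconstruct_table(a, ror, prr, chi2)
        # the reconstruction reproduces the rounded statistics
        assert round(compute_ror(rec)[0], 2) == pytest.approx(ror, abs=0.011)
        assert round(compute_prr(rec), 2) == pytest.approx(prr, abs=0.011)
        assert compute_chi2(rec) == pytest.approx(chi2, rel=0.01)
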