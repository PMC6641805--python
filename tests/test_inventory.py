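"""Inventory ledger, filled-to-max requirement, adequacy, truncation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from implantflow import (
    Brand,
    InsufficientHorizonError,
    MonthGrid,
    MonthlySeries,
    ProcurementEvent,
    SupplyChainDesign,
    filled_to_max,
    impute_inventory,
    month,
    pct_difference,
    truncate_analysis_window,
)


def ev(m, qty):
    return ProcurementEvent(m, qty, Brand.ETONOGESTREL_1ROD)


class TestImputeInventory:
    def test_two_month_worked_ledger(self):
        grid = MonthGrid("2010-01", 2)
        ledger = impute_inventory(0, [ev("2010-01", 100)],
                                  MonthlySeries(grid, [40.0, 30.0]))
        assert list(ledger.ending) == [60.0, 30.0]
        assert list(ledger.beginning) == [0.0, 60.0]

    def test_no_flows_is_identity(self):
        grid = MonthGrid("2010-01", 6)
        ledger = impute_inventory(500, [], MonthlySeries.constant(grid, 0.0))
        assert np.all(ledger.ending == 500)

    def test_event_before_grid_rejected(self):
        grid = MonthGrid("2010-02", 3)
        with pytest.raises(ValueError, match="predates grid start"):
            impute_inventory(0, [ev("2010-01", 10)], MonthlySeries.constant(grid, 1.0))

    def test_stockouts_flagged_and_retained(self):
        grid = MonthGrid("2010-01", 3)
        with pytest.warns(UserWarning, match="stockout"):
            ledger = impute_inventory(0, [ev("2010-02", 100)],
                                      MonthlySeries(grid, [50.0, 10.0, 10.0]))
        assert ledger.ending[0] == -50
        assert ledger.stockout_months == [month("2010-01")]

    def test_clamp_option_floors_at_zero(self):
        grid = MonthGrid("2010-01", 3)
        ledger = impute_inventory(0, [ev("2010-02", 100)],
                                  MonthlySeries(grid, [50.0, 10.0, 10.0]),
                                  clamp_negative=True)
        assert list(ledger.ending) == [0.0, 90.0, 80.0]

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_sixty_month_ledger_matches_cumsum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = MonthGrid("2010-01", 60)
        cons = rng.integers(0, 5_000, 60).astype(float)
        receipt_months = rng.choice(60, size=8, replace=False)
        quantities = rng.integers(0, 40_000, 8)
        events = [ev(grid.index[int(m)], int(q)) for m, q in zip(receipt_months, quantities)]
        begin = float(rng.integers(0, 10_000))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ledger = impute_inventory(begin, events, MonthlySeries(grid, cons))
        receipts = np.zeros(60)
        for m, q in zip(receipt_months, quantities):
            receipts[m] += q
        expected = begin + np.cumsum(receipts - cons)
        assert np.array_equal(ledger.ending, expected)
        # conservation over the whole window, exact in integer arithmetic
        assert ledger.ending[-1] - ledger.beginning[0] == receipts.sum() - cons.sum()


class TestFilledToMax:
    def test_constant_demand_18_months(self, design18):
        grid = MonthGrid("2010-01", 36)
        fm = filled_to_max(MonthlySeries.constant(grid, 15_000), design18)
        evaluable = fm.values[~np.isnan(fm.values)]
        assert np.allclose(evaluable, 270_000)
        assert len(evaluable) == 36 - 18 + 1

    def test_linear_growth_75pct_rounds_to_370k(self, design18):
        grid = MonthGrid("2010-01", 18)
        cons = MonthlySeries(grid, np.linspace(15_000, 26_250, 18))
        fm = filled_to_max(cons, design18)
        assert round(fm.values[0], -4) == 370_000
        assert fm.values[0] - 270_000 == pytest.approx(100_000, abs=5_000)

    def test_zero_consumption_needs_zero_inventory(self, design18):
        grid = MonthGrid("2010-01", 24)
        fm = filled_to_max(MonthlySeries.constant(grid, 0.0), design18)
        assert np.all(fm.values[~np.isnan(fm.values)] == 0)

    def test_fractional_months_prorated(self):
        design = SupplyChainDesign(levels=[("central", 2.5)])
        grid = MonthGrid("2010-01", 4)
        fm = filled_to_max(MonthlySeries(grid, [100.0, 200.0, 400.0, 800.0]), design)
        assert fm.values[0] == pytest.approx(100 + 200 + 0.5 * 400)
        assert fm.values[1] == pytest.approx(200 + 400 + 0.5 * 800)
        assert np.isnan(fm.values[2])

    @given(st.floats(min_value=1, max_value=24), st.floats(min_value=1, max_value=1e5))
    @settings(deadline=None)
    def test_constant_demand_closed_form(self, M, d):
        design = SupplyChainDesign(levels=[("sys", M)])
        grid = MonthGrid("2010-01", 30)
        fm = filled_to_max(MonthlySeries.constant(grid, d), design)
        evaluable = fm.values[~np.isnan(fm.values)]
        assert evaluable.size > 0
        assert np.allclose(evaluable, M * d, rtol=1e-12)

    def test_monotone_in_design_total_and_demand_scale(self):
        grid = MonthGrid("2010-01", 40)
        rng = np.random.default_rng(3)
        cons = MonthlySeries(grid, rng.uniform(100, 10_000, 40))
        small = filled_to_max(cons, SupplyChainDesign(levels=[("sys", 10)])).values
        large = filled_to_max(cons, SupplyChainDesign(levels=[("sys", 14)])).values
        mask = ~np.isnan(large)
        assert np.all(large[mask] >= small[mask])
        doubled = filled_to_max(
            MonthlySeries(grid, cons.values * 2),
            SupplyChainDesign(levels=[("sys", 10)]),
        ).values
        mask = ~np.isnan(doubled)
        assert np.allclose(doubled[mask], 2 * small[mask])

    def test_no_horizon_at_all_warns_empty(self, design18):
        grid = MonthGrid("2010-01", 6)
        with pytest.warns(UserWarning, match="no month has"):
            fm = filled_to_max(MonthlySeries.constant(grid, 100.0), design18)
        assert np.all(np.isnan(fm.values))


class TestPctDifference:
    def _pair(self, imputed, fm):
        grid = MonthGrid("2010-01", len(imputed))
        return (MonthlySeries(grid, imputed, "inventory"),
                MonthlySeries(grid, fm, "inventory"))

    def test_equality_means_accurate(self):
        a = pct_difference(*self._pair([100.0, 200.0], [100.0, 200.0]))
        assert np.allclose(a.pct_difference, 0.0)

    def test_surplus_and_deficit_signs(self):
        a = pct_difference(*self._pair([150.0, 0.0], [100.0, 100.0]))
        assert a.pct_difference[0] == pytest.approx(50.0)   # over-procurement
        assert a.pct_difference[1] == pytest.approx(-100.0)  # under-procurement
        assert np.all(np.sign(a.pct_difference) == np.sign(a.surplus_units))

    def test_zero_benchmark_month_excluded(self):
        a = pct_difference(*self._pair([100.0, 100.0], [0.0, 100.0]))
        assert np.isnan(a.pct_difference[0])
        assert a.excluded_months == [month("2010-01")]


class TestTruncateAnalysisWindow:
    def _series(self):
        grid = MonthGrid("2010-01", 96)  # Jan 2010 .. Dec 2017
        return MonthlySeries(grid, np.arange(96, dtype=float), "ratio")

    def test_pakistan_rule_18_months(self):
        design = SupplyChainDesign(levels=[("sys", 18)])
        out = truncate_analysis_window(self._series(), design, "2017-12")
        assert out.grid.end == month("2016-06")
        assert out.grid.start == month("2010-01")

    def test_zero_months_of_stock_leaves_window_unchanged(self):
        out = truncate_analysis_window(self._series(), 0.0, "2017-12")
        assert out.grid.end == month("2017-12")

    def test_22_months_ends_february_2016(self):
        # date-arithmetic oracle: Dec 2017 minus 22 months is Feb 2016
        design = SupplyChainDesign(levels=[("sys", 22)])
        out = truncate_analysis_window(self._series(), design, "2017-12")
        assert out.grid.end == month("2016-02")

    def test_fractional_total_rounds_up(self):
        design = SupplyChainDesign(levels=[("sys", 17.5)])
        out = truncate_analysis_window(self._series(), design, "2017-12")
        assert out.grid.end == month("2016-06")

    def test_empty_window_suggests_longer_series(self):
        grid = MonthGrid("2017-01", 12)
        series = MonthlySeries(grid, np.zeros(12), "ratio")
        design = SupplyChainDesign(levels=[("sys", 18)])
        with pytest.raises(InsufficientHorizonError, match="longer input series"):
            truncate_analysis_window(series, design, "2017-12")
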