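"""Survey interpolation, user estimation, and CYP-based conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from implantflow import (
    Brand,
    BrandMix,
    MonthGrid,
    MonthlySeries,
    SurveyPoint,
    blend_cyp,
    estimate_users,
    interpolate_surveys,
    users_to_products_annual,
    users_to_products_monthly,
)
from implantflow.demand import CYP_YEARS


def survey(m, pop, cpr, mix=1.0):
    return SurveyPoint(m, pop, implant_cpr=cpr, source_mix_public_ngo=mix)


def piecewise_linear_oracle(xs, xp, yp):
    """Independent segment-by-segment evaluation with flat-hold ends."""
    out = []
    for x in xs:
        if x <= xp[0]:
            out.append(yp[0])
        elif x >= xp[-1]:
            out.append(yp[-1])
        else:
            for (x0, y0), (x1, y1) in zip(zip(xp, yp), zip(xp[1:], yp[1:])):
                if x0 <= x <= x1:
                    out.append(y0 + (y1 - y0) * (x - x0) / (x1 - x0))
                    break
    return np.array(out)


class TestInterpolateSurveys:
    def test_equal_values_give_constant_series(self):
        grid = MonthGrid("2010-01", 12)
        pts = [survey("2010-03", 1e6, 0.02), survey("2010-09", 1e6, 0.02)]
        out = interpolate_surveys(pts, grid)
        assert np.allclose(out["implant_cpr"].values, 0.02)
        assert np.allclose(out["population_wra"].values, 1e6)

    def test_midpoint_of_a_line(self):
        grid = MonthGrid("2010-01", 6)
        pts = [survey("2010-01", 10, 0.0), survey("2010-05", 20, 0.0)]
        out = interpolate_surveys(pts, grid)
        # months 0 and 4 anchor the line; month 2 sits halfway
        assert out["population_wra"]["2010-03"] == pytest.approx(15.0)

    def test_flat_hold_outside_survey_range(self):
        grid = MonthGrid("2010-01", 12)
        pts = [survey("2010-04", 100, 0.01), survey("2010-08", 200, 0.03)]
        out = interpolate_surveys(pts, grid)
        assert out["population_wra"]["2010-01"] == pytest.approx(100.0)
        assert out["population_wra"]["2010-12"] == pytest.approx(200.0)

    @settings(deadline=None)
    @given(values=st.lists(st.floats(min_value=0, max_value=1e7), min_size=5, max_size=5),
           data=st.data())
    def test_matches_independent_piecewise_oracle(self, values, data):
        n = 36
        months = sorted(data.draw(st.lists(
            st.integers(min_value=0, max_value=n - 1), min_size=5, max_size=5, unique=True)))
        grid = MonthGrid("2010-01", n)
        pts = [survey(grid.index[m], v, 0.0) for m, v in zip(months, values)]
        out = interpolate_surveys(pts, grid)
        expected = piecewise_linear_oracle(np.arange(n), months, values)
        assert np.allclose(out["population_wra"].values, expected)

    def test_single_point_warns_and_holds_constant(self):
        grid = MonthGrid("2010-01", 6)
        with pytest.warns(UserWarning, match="single survey point"):
            out = interpolate_surveys([survey("2010-03", 5e5, 0.02)], grid)
        assert np.allclose(out["implant_cpr"].values, 0.02)

    def test_duplicate_months_rejected(self):
        grid = MonthGrid("2010-01", 6)
        pts = [survey("2010-02", 1, 0.0), survey("2010-02", 2, 0.0)]
        with pytest.raises(ValueError, match="duplicate"):
            interpolate_surveys(pts, grid)

    def test_point_outside_grid_rejected(self):
        grid = MonthGrid("2010-01", 6)
        pts = [survey("2009-12", 1, 0.0), survey("2010-02", 2, 0.0)]
        with pytest.raises(ValueError, match="outside grid"):
            interpolate_surveys(pts, grid)


class TestEstimateUsers:
    def test_direct_product(self):
        grid = MonthGrid("2010-01", 3)
        users = estimate_users(
            MonthlySeries.constant(grid, 1_000_000, "users"),
            mcpr=MonthlySeries.constant(grid, 0.20, "ratio"),
            implant_share=MonthlySeries.constant(grid, 0.10, "ratio"),
            source_mix=MonthlySeries.constant(grid, 1.0, "ratio"),
        )
        assert np.allclose(users.values, 20_000)

    def test_zero_share_gives_zero_users(self):
        grid = MonthGrid("2010-01", 3)
        users = estimate_users(
            MonthlySeries.constant(grid, 1e6, "users"),
            mcpr=MonthlySeries.constant(grid, 0.2, "ratio"),
            implant_share=MonthlySeries.constant(grid, 0.0, "ratio"),
        )
        assert np.all(users.values == 0)

    def test_cpr_variant_matches_mcpr_times_share(self):
        grid = MonthGrid("2010-01", 6)
        rng = np.random.default_rng(7)
        pop = MonthlySeries(grid, rng.uniform(1e5, 1e6, 6), "users")
        mcpr = MonthlySeries(grid, rng.uniform(0.1, 0.3, 6), "ratio")
        share = MonthlySeries(grid, rng.uniform(0.05, 0.2, 6), "ratio")
        cpr = MonthlySeries(grid, mcpr.values * share.values, "ratio")
        a = estimate_users(pop, mcpr=mcpr, implant_share=share)
        b = estimate_users(pop, implant_cpr=cpr)
        assert np.allclose(a.values, b.values)


class TestBlendCyp:
    def test_blended_25_75_mix(self):
        mix = BrandMix({Brand.LEVONORGESTREL_2ROD: 0.25, Brand.ETONOGESTREL_1ROD: 0.75})
        cf = blend_cyp(mix)
        assert cf.blended_cyp == pytest.approx(2.825)
        assert round(cf.annual_cf, 3) == 0.354

    @pytest.mark.parametrize(
        "brand, cyp, annual_2dp, months",
        [
            (Brand.ETONOGESTREL_1ROD, 2.5, 0.40, 30.0),
            (Brand.LEVONORGESTREL_2ROD, 3.8, 0.26, 45.6),
        ],
    )
    def test_single_brand_factors_and_replacement_intervals(self, brand, cyp, annual_2dp, months):
        cf = blend_cyp(BrandMix({brand: 1.0}))
        assert cf.blended_cyp == cyp
        assert round(cf.annual_cf, 2) == annual_2dp
        assert cf.months_of_protection == pytest.approx(months)

    def test_levonorgestrel_monthly_factor(self):
        cf = blend_cyp(BrandMix({Brand.LEVONORGESTREL_2ROD: 1.0}))
        assert round(cf.monthly_cf, 3) == 0.022

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            BrandMix({Brand.ETONOGESTREL_1ROD: 0.5})

    @given(st.floats(min_value=0, max_value=1))
    def test_blend_lies_between_brand_cyps(self, f):
        mix = BrandMix({Brand.ETONOGESTREL_1ROD: f, Brand.LEVONORGESTREL_2ROD: 1 - f})
        cf = blend_cyp(mix)
        assert 2.5 <= cf.blended_cyp <= 3.8
        assert cf.annual_cf * cf.blended_cyp == pytest.approx(1.0, abs=1e-12)


class TestUsersToProducts:
    def test_annual_steady_state_is_replacement_only(self):
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 1.0}))
        assert users_to_products_annual(25_000, 25_000, cf) == pytest.approx(10_000)

    def test_annual_pure_growth(self):
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 1.0}))
        assert users_to_products_annual(0, 5_000, cf) == pytest.approx(5_000)

    @given(st.floats(min_value=0, max_value=1e6), st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=0.01, max_value=1))
    def test_annual_matches_literal_formula(self, uy1, uy2, f):
        mix = BrandMix({Brand.ETONOGESTREL_1ROD: f, Brand.LEVONORGESTREL_2ROD: 1 - f})
        cf = blend_cyp(mix)
        expected = (uy2 - uy1) + uy1 * (1.0 / cf.blended_cyp)
        assert users_to_products_annual(uy1, uy2, cf) == pytest.approx(expected)

    def test_constant_users_monthly_consumption(self):
        grid = MonthGrid("2010-01", 12)
        users = MonthlySeries.constant(grid, 30_000, "users")
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 1.0}))
        products = users_to_products_monthly(users, cf)
        assert np.allclose(products.values, 1_000)  # 30,000 x 0.4 / 12

    def test_monthly_aggregates_to_annual_for_linear_users(self):
        """Summed over a year, the monthly adaptation reproduces the annual
        formula (with yearly user bases read as within-year means)."""
        grid = MonthGrid("2010-01", 25)
        u = np.linspace(10_000, 34_000, 25)  # linear growth across 2 years
        users = MonthlySeries(grid, u, "users")
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 0.6,
                                 Brand.LEVONORGESTREL_2ROD: 0.4}))
        monthly = users_to_products_monthly(users, cf)
        total_y1 = monthly.values[:12].sum()
        uy1, uy2 = u[:12].mean(), u[12:24].mean()
        assert total_y1 == pytest.approx(users_to_products_annual(uy1, uy2, cf), rel=1e-9)

    def test_negative_months_flagged_not_clamped(self):
        grid = MonthGrid("2010-01", 3)
        users = MonthlySeries(grid, [10_000, 100, 100], "users")
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 1.0}))
        with pytest.warns(UserWarning, match="negative demographic consumption"):
            products = users_to_products_monthly(users, cf)
        assert products.values[0] < 0
        clamped = users_to_products_monthly(users, cf, clamp_negative=True)
        assert np.all(clamped.values >= 0)

    @given(st.floats(min_value=1.01, max_value=3.0))
    @settings(deadline=None)
    def test_uniformly_larger_users_never_need_fewer_products(self, scale):
        # Scaling a growing programme up can only increase total product
        # needs (for a declining one the growth term may dominate with the
        # opposite sign, which is why negative months are flagged).
        grid = MonthGrid("2010-01", 24)
        rng = np.random.default_rng(11)
        u = np.sort(rng.uniform(1e3, 1e5, 24))
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 1.0}))
        base = users_to_products_monthly(MonthlySeries(grid, u, "users"), cf)
        bigger = users_to_products_monthly(MonthlySeries(grid, u * scale, "users"), cf)
        assert bigger.values.sum() >= base.values.sum()

    def test_single_month_grid_rejected(self):
        users = MonthlySeries(MonthGrid("2010-01", 1), [100.0], "users")
        cf = blend_cyp(BrandMix({Brand.ETONOGESTREL_1ROD: 1.0}))
        with pytest.raises(ValueError, match="2 months"):
            users_to_products_monthly(users, cf)
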