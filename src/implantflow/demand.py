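"""Demographic demand estimation: surveys -> users -> monthly consumption.

The chain has three steps:

1.  Sparse survey observations (population of women of reproductive age,
    mCPR, implant share of method mix, public+NGO source mix) are linearly
    interpolated between their midpoint months, and held flat before the
    first and after the last observation.

2.  Implant users each month are the product
    ``population_wra x mCPR x implant_share x source_mix`` (or with
    ``implant_cpr`` substituting for ``mCPR x implant_share``).

3.  Users convert to devices via couple-years of protection (CYP): a
    brand's CYP is the years of contraceptive protection one device
    provides (2.5 for the 1-rod etonogestrel product, 3.8 for the 2-rod
    levonorgestrel product), so ``1/CYP`` devices sustain one user-year.
    The annual requirement for a user base moving from UY1 to UY2 is
    ``(UY2 - UY1) + UY1 x CYP_CF``: new adopters each need a device, and a
    fraction ``CYP_CF`` of the existing base replaces theirs. The monthly
    adaptation replaces the year-over-year growth with month-over-month
    growth and spreads the replacement term over 12 months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .grids import MonthGrid, MonthlySeries
from .types import Brand, BrandMix, SurveyPoint

__all__ = [
    "CYP_YEARS",
    "CypFactors",
    "blend_cyp",
    "interpolate_surveys",
    "estimate_users",
    "users_to_products_annual",
    "users_to_products_monthly",
    "demographic_consumption",
]

#: Couple-years of protection per device, by brand.
CYP_YEARS: Mapping[Brand, float] = {
    Brand.ETONOGESTREL_1ROD: 2.5,
    Brand.LEVONORGESTREL_2ROD: 3.8,
}


@dataclass(frozen=True)
class CypFactors:
    """Blended couple-years-of-protection factors for a brand mix.

    Attributes
    ----------
    blended_cyp : float
        Mix-weighted years of protection per device.
    annual_cf : float
        Devices per user-year, ``1 / blended_cyp``.
    months_of_protection : float
        Replacement interval in months, ``blended_cyp x 12``.
    monthly_cf : float
        Devices per user-month, ``1 / months_of_protection``.
    """

    blended_cyp: float

    def __post_init__(self) -> None:
        if self.blended_cyp <= 0:
            raise ValueError("blended CYP must be positive")

    @property
    def annual_cf(self) -> float:
        return 1.0 / self.blended_cyp

    @property
    def months_of_protection(self) -> float:
        return self.blended_cyp * 12.0

    @property
    def monthly_cf(self) -> float:
        return 1.0 / self.months_of_protection


def blend_cyp(
    mix: BrandMix, cyps: Mapping[Brand, float] = CYP_YEARS
) -> CypFactors:
    """Blend per-brand CYPs by the market's brand mix.

    The years of protection are blended first and then inverted; blending
    the conversion factors directly would misweight the faster-replacing
    brand. A 25% levonorgestrel / 75% etonogestrel mix gives
    ``0.25 x 3.8 + 0.75 x 2.5 = 2.825`` years and a conversion factor of
    ``1/2.825 ~ 0.354`` devices per user-year.
    """
    blended = sum(mix[b] * cyp for b, cyp in cyps.items())
    return CypFactors(blended_cyp=blended)


def interpolate_surveys(
    points: Sequence[SurveyPoint], grid: MonthGrid
) -> dict[str, MonthlySeries]:
    """Expand sparse survey points to monthly series on ``grid``.

    Piecewise-linear between adjacent midpoint months; flat-hold before the
    first and after the last point (extrapolating uptake trends past the
    observed range would overstate demand). A single point yields constant
    series and a warning.

    Returns a dict with keys ``population_wra``, ``implant_cpr`` (the
    effective implant prevalence, whichever parameterisation each survey
    used) and ``source_mix``.
    """
    if not points:
        raise ValueError("at least one survey point is required")
    pts = sorted(points, key=lambda p: p.month)
    months = [p.month for p in pts]
    if len(set(months)) != len(months):
        dupes = sorted({m for m in months if months.count(m) > 1})
        raise ValueError(f"duplicate survey months: {[str(m) for m in dupes]}")
    outside = [m for m in months if m not in grid]
    if outside:
        raise ValueError(
            f"survey months outside grid {grid.start}..{grid.end}: {[str(m) for m in outside]}"
        )
    if len(pts) == 1:
        warnings.warn(
            f"single survey point ({pts[0].month}); all demographic series held constant",
            stacklevel=2,
        )

    x = np.array([grid.offset(p.month) for p in pts], dtype=float)
    xs = np.arange(len(grid), dtype=float)

    def interp(vals: Sequence[float], kind: str) -> MonthlySeries:
        # np.interp flat-holds outside the data range, matching the
        # extrapolation rule.
        return MonthlySeries(grid, np.interp(xs, x, np.asarray(vals, dtype=float)), kind=kind)

    return {
        "population_wra": interp([p.population_wra for p in pts], "users"),
        "implant_cpr": interp([p.effective_implant_cpr for p in pts], "ratio"),
        "source_mix": interp([p.source_mix_public_ngo for p in pts], "ratio"),
    }


def estimate_users(
    population_wra: MonthlySeries,
    mcpr: MonthlySeries | None = None,
    implant_share: MonthlySeries | None = None,
    source_mix: MonthlySeries | None = None,
    implant_cpr: MonthlySeries | None = None,
) -> MonthlySeries:
    """Monthly public+NGO-sector implant users.

    ``users[m] = population_wra[m] x mCPR[m] x implant_share[m] x source_mix[m]``,
    or with ``implant_cpr`` replacing the mCPR x share product. Source mix
    defaults to 1 (all users reached through the modelled channels).
    """
    if implant_cpr is not None:
        if mcpr is not None or implant_share is not None:
            raise ValueError("supply either implant_cpr or (mcpr & implant_share), not both")
        population_wra.same_grid(implant_cpr)
        prevalence = implant_cpr.values
    else:
        if mcpr is None or implant_share is None:
            raise ValueError("mcpr and implant_share are both required without implant_cpr")
        population_wra.same_grid(mcpr)
        population_wra.same_grid(implant_share)
        prevalence = mcpr.values * implant_share.values
    users = population_wra.values * prevalence
    if source_mix is not None:
        population_wra.same_grid(source_mix)
        users = users * source_mix.values
    return MonthlySeries(population_wra.grid, users, kind="users")


def users_to_products_annual(users_y1: float, users_y2: float, cf: CypFactors) -> float:
    """Devices required for one year: ``(UY2 - UY1) + UY1 x CYP_CF``.

    Growth supplies every net new user with a device; a fraction
    ``annual_cf`` of the year-1 base replaces an expiring device. Negative
    results under steep decline are returned as-is.
    """
    if users_y1 < 0 or users_y2 < 0:
        raise ValueError("user counts must be non-negative")
    return (users_y2 - users_y1) + users_y1 * cf.annual_cf


def users_to_products_monthly(
    users: MonthlySeries, cf: CypFactors, clamp_negative: bool = False
) -> MonthlySeries:
    """Monthly device consumption from a user series.

    ``product[m] = (users[m+1] - users[m]) + users[m] x annual_cf / 12``.
    The final month has no successor, so its growth term uses a flat-hold
    of users (i.e. zero growth). Aggregated over a year this reproduces the
    annual formula. Months of user decline can yield negative consumption;
    by default these are retained (downstream ledgers stay conservative),
    ``clamp_negative=True`` floors them at zero.
    """
    if users.kind != "users":
        raise ValueError(f"expected a users series, got kind={users.kind!r}")
    if len(users) < 2:
        raise ValueError("monthly conversion needs a grid of at least 2 months")
    u = users.values
    growth = np.append(np.diff(u), 0.0)  # flat-hold: last month's growth is 0
    products = growth + u * (cf.annual_cf / 12.0)
    if clamp_negative:
        products = np.maximum(products, 0.0)
    elif np.any(products < 0):
        warnings.warn(
            f"{int(np.sum(products < 0))} months of negative demographic consumption "
            "(user decline); retained, pass clamp_negative=True to floor at zero",
            stacklevel=2,
        )
    return MonthlySeries(users.grid, products, kind="consumption")


def demographic_consumption(
    points: Sequence[SurveyPoint],
    grid: MonthGrid,
    cf: CypFactors,
    clamp_negative: bool = False,
) -> MonthlySeries:
    """Full chain: surveys -> interpolated rates -> users -> consumption."""
    series = interpolate_surveys(points, grid)
    users = estimate_users(
        series["population_wra"],
        implant_cpr=series["implant_cpr"],
        source_mix=series["source_mix"],
    )
    return users_to_products_monthly(users, cf, clamp_negative=clamp_negative)
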