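"""Synthetic country scenarios with known ground truth.

Real country datasets behind this kind of analysis (logistics-system
extracts, procurement databases) are confidential, so every pipeline stage
is exercised against generated scenarios that emulate their shape: several
years of monthly data, demand growing steeply as a new method scales up
(the motivating programmes saw consumption rise ~75% over 18 months),
demographic rates observed only at a handful of survey midpoints, and
procurement arriving in one or two lumpy shipments a year.

The generator first lays down smooth *true* monthly trajectories
(population, mCPR, implant share), derives true users and — through the
same CYP conversion the estimator uses — true consumption, then degrades
them into the observables: dispensed-to-client counts with multiplicative
log-normal noise, surveys sampling the true rates at the survey months,
and procurement events following a policy. All randomness comes from one
seeded generator per scenario.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .demand import CYP_YEARS, blend_cyp, estimate_users, users_to_products_monthly
from .grids import MonthGrid, MonthlySeries, month
from .inventory import InventoryLedger, filled_to_max, impute_inventory
from .io import Scenario
from .types import ArrivalSource, Brand, BrandMix, ProcurementEvent, SupplyChainDesign, SurveyPoint

__all__ = [
    "Trajectory",
    "ProcurementPolicy",
    "ScenarioSpec",
    "GroundTruth",
    "generate_scenario",
    "paper_like_scenario",
]


@dataclass(frozen=True)
class Trajectory:
    """A rate's path over the scenario: ``start`` to ``end``, linearly or
    along a logistic (S-shaped scale-up, steepest mid-scenario)."""

    start: float
    end: float
    shape: str = "linear"  # linear | logistic
    steepness: float = 8.0  # logistic only; larger = sharper uptake

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "logistic"):
            raise ValueError(f"unknown trajectory shape {self.shape!r}")

    def values(self, n: int) -> np.ndarray:
        if n == 1:
            return np.array([self.start])
        t = np.linspace(0.0, 1.0, n)
        if self.shape == "linear":
            f = t
        else:
            raw = 1.0 / (1.0 + np.exp(-self.steepness * (t - 0.5)))
            f = (raw - raw[0]) / (raw[-1] - raw[0])
        return self.start + (self.end - self.start) * f


class ProcurementPolicy(str, enum.Enum):
    FILL_TO_MAX_EXACT = "fill_to_max_exact"  # monthly receipts track filled-to-max exactly
    FIXED_SCHEDULE = "fixed_schedule"  # lumpy shipments covering the next interval
    NOISY = "noisy"  # fixed schedule with log-normal quantity noise


def _default_design() -> SupplyChainDesign:
    # 18 months of stock across five levels, the canonical worked system.
    return SupplyChainDesign(
        levels=[
            ("central", 5.0),
            ("regional", 4.0),
            ("district", 4.0),
            ("sdp", 4.0),
            ("community_health_worker", 1.0),
        ]
    )


def _default_brand_mix() -> BrandMix:
    return BrandMix({Brand.ETONOGESTREL_1ROD: 0.75, Brand.LEVONORGESTREL_2ROD: 0.25})


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of a synthetic country.

    Defaults emulate the study setting: an 8-year (96-month) horizon, a
    population of 8 million women of reproductive age growing 2.8%/year,
    implant prevalence scaling up steeply (mCPR 15%→28%, implant share of
    method mix 5%→22% along a logistic), 90% of users served via
    public+NGO channels, a 75/25 etonogestrel/levonorgestrel brand mix, an
    18-months-of-stock five-level supply chain, demographic surveys at two
    midpoints roughly three years apart, and twice-yearly shipments.
    """

    seed: int = 0
    start_month: str = "2010-01"
    n_months: int = 96
    population_wra: float = 8_000_000.0
    population_growth_annual: float = 0.028
    mcpr: Trajectory = field(default_factory=lambda: Trajectory(0.15, 0.28, "logistic"))
    implant_share: Trajectory = field(default_factory=lambda: Trajectory(0.05, 0.22, "logistic"))
    source_mix: float = 0.9
    brand_mix: BrandMix = field(default_factory=_default_brand_mix)
    design: SupplyChainDesign = field(default_factory=_default_design)
    survey_months: Sequence[int] = (12, 48)  # 0-based offsets into the grid
    survey_noise_cv: float = 0.0
    procurement_policy: ProcurementPolicy = ProcurementPolicy.FIXED_SCHEDULE
    shipment_interval_months: int = 6
    procurement_noise_cv: float = 0.2
    dispensed_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_months < 2:
            raise ValueError("a scenario needs at least 2 months")
        for name in ("dispensed_noise_cv", "survey_noise_cv", "procurement_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for traj in (self.mcpr, self.implant_share):
            if not (0 <= traj.start <= 1 and 0 <= traj.end <= 1):
                raise ValueError(f"trajectory endpoints outside [0, 1]: {traj}")
        if not 0 <= self.source_mix <= 1:
            raise ValueError("source_mix must be in [0, 1]")
        if any(not 0 <= s < self.n_months for s in self.survey_months):
            raise ValueError("survey_months must be offsets within the grid")
        object.__setattr__(self, "procurement_policy", ProcurementPolicy(self.procurement_policy))


@dataclass
class GroundTruth:
    """The generator's noiseless internals, for recovery tests."""

    users: MonthlySeries
    consumption: MonthlySeries  # true (unrounded) monthly device consumption
    ledger: InventoryLedger  # true inventory under the generated procurement
    rates: dict  # population_wra / mcpr / implant_share arrays


def _lognormal_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def _split_by_brand(quantity: int, mix: BrandMix) -> list[tuple[Brand, int]]:
    """Integer-split a shipment by brand mix, remainder to the largest share."""
    brands = sorted(mix.fractions, key=lambda b: -mix[b])
    out, assigned = [], 0
    for b in brands[:-1]:
        q = int(round(quantity * mix[b]))
        out.append((b, q))
        assigned += q
    out.append((brands[-1], quantity - assigned))
    return [(b, q) for b, q in out if q > 0]


def generate_scenario(spec: ScenarioSpec) -> tuple[Scenario, GroundTruth]:
    """Deterministically generate a scenario and its ground truth from a spec."""
    rng = np.random.default_rng(spec.seed)
    grid = MonthGrid(spec.start_month, spec.n_months)
    n = spec.n_months

    # true monthly trajectories
    t_months = np.arange(n)
    pop = spec.population_wra * (1.0 + spec.population_growth_annual) ** (t_months / 12.0)
    mcpr = spec.mcpr.values(n)
    share = spec.implant_share.values(n)
    rates = {"population_wra": pop, "mcpr": mcpr, "implant_share": share}

    users = estimate_users(
        MonthlySeries(grid, pop, kind="users"),
        mcpr=MonthlySeries(grid, mcpr, kind="ratio"),
        implant_share=MonthlySeries(grid, share, kind="ratio"),
        source_mix=MonthlySeries.constant(grid, spec.source_mix, kind="ratio"),
    )
    cf = blend_cyp(spec.brand_mix)
    true_consumption = users_to_products_monthly(users, cf)

    # observables: dispensed counts (noisy, integer) and surveys
    noise = _lognormal_factors(rng, n, spec.dispensed_noise_cv)
    dispensed_vals = np.round(np.maximum(true_consumption.values * noise, 0.0))
    dispensed = MonthlySeries(grid, dispensed_vals, kind="consumption")

    surveys = []
    for s in spec.survey_months:
        sf = _lognormal_factors(rng, 3, spec.survey_noise_cv)
        surveys.append(
            SurveyPoint(
                month=grid.index[s],
                population_wra=pop[s] * sf[0],
                mcpr=min(1.0, mcpr[s] * sf[1]),
                implant_share=min(1.0, share[s] * sf[2]),
                source_mix_public_ngo=spec.source_mix,
            )
        )

    events = _generate_procurement(spec, rng, grid, dispensed)

    scenario = Scenario(
        grid=grid,
        design=spec.design,
        events=events,
        dispensed=dispensed,
        surveys=surveys,
        brand_mix=spec.brand_mix,
        beginning_balance=0.0,
        name=f"synthetic-seed{spec.seed}",
    )
    ledger = impute_inventory(0.0, events, dispensed)
    truth = GroundTruth(users=users, consumption=true_consumption, ledger=ledger, rates=rates)
    return scenario, truth


def _generate_procurement(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    grid: MonthGrid,
    dispensed: MonthlySeries,
) -> list[ProcurementEvent]:
    cons = dispensed.values
    n = len(cons)
    receipts = np.zeros(n)

    if spec.procurement_policy is ProcurementPolicy.FILL_TO_MAX_EXACT:
        # Each month's receipt restores the ending balance exactly to the
        # filled-to-max requirement; outside the evaluable window no stock
        # is added. Integer consumption keeps the identity exact.
        fm = filled_to_max(dispensed, spec.design).values
        bal = 0.0
        for m in range(n):
            if np.isnan(fm[m]):
                break
            req = fm[m] - bal + cons[m]
            if req < 0:  # projected demand fell faster than one month's offtake
                req = 0.0
            receipts[m] = req
            bal = bal + req - cons[m]
    else:
        interval = spec.shipment_interval_months
        for m in range(0, n, interval):
            qty = float(np.sum(cons[m : m + interval]))
            if spec.procurement_policy is ProcurementPolicy.NOISY:
                qty *= _lognormal_factors(rng, 1, spec.procurement_noise_cv)[0]
            receipts[m] = round(qty)

    events: list[ProcurementEvent] = []
    for m in np.nonzero(receipts > 0)[0]:
        for brand, qty in _split_by_brand(int(round(receipts[m])), spec.brand_mix):
            events.append(
                ProcurementEvent(
                    arrival_month=grid.index[int(m)],
                    quantity=qty,
                    brand=brand,
                    arrival_source=ArrivalSource.REPORTED,
                )
            )
    return events


def paper_like_scenario(constant_demand: bool = False) -> Scenario:
    """The worked 18-months-of-stock example as a packaged fixture.

    An 18-month series for a five-level system totalling 18 months of
    stock. By default demand grows linearly by 75%, from 15,000 units in
    month 1 to 26,250 in month 18 (filled-to-max at month 1 ~ 370,000
    units); with ``constant_demand=True`` it stays at 15,000/month
    (filled-to-max 270,000).
    """
    grid = MonthGrid("2010-01", 18)
    if constant_demand:
        values = np.full(18, 15_000.0)
    else:
        values = np.linspace(15_000.0, 26_250.0, 18)
    dispensed = MonthlySeries(grid, values, kind="consumption")
    total = int(round(values.sum()))
    events = [
        ProcurementEvent(grid.start, total, Brand.ETONOGESTREL_1ROD, ArrivalSource.REPORTED)
    ]
    return Scenario(
        grid=grid,
        design=_default_design(),
        events=events,
        dispensed=dispensed,
        brand_mix=_default_brand_mix(),
        name="worked-example-constant" if constant_demand else "worked-example-growth",
    )
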