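"""Summary statistics for the three adequacy questions, plus validation.

1.  *Procurement accuracy* — mean/SD/min/max of the monthly percentage
    difference between imputed and filled-to-max inventory.
2.  *Inventory-to-consumption ratio* — a month's filled-to-max requirement
    as a percentage of the same month's consumption; the question is
    whether a standard multiplier of consumption could stand in for a
    supply-chain model (it cannot: under growth the ratio moves with the
    growth rate, not just the design).
3.  *Demographic vs dispensed* — demographic consumption estimates as a
    percentage of dispensed-to-client data; a mean below 100% is a
    demographic forecast error of ``100% - mean``.

Model validation correlates imputed ending balances with physically
reported system inventory at the snapshot months a country provides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Month, MonthGrid, MonthlySeries, month
from .inventory import AdequacySeries, InventoryLedger

__all__ = [
    "SummaryStats",
    "summarize",
    "procurement_accuracy",
    "inventory_to_consumption_ratio",
    "demographic_vs_dispensed",
    "validate_against_reported",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean, sample SD, min, max over the non-excluded months of a window."""

    mean: float
    sd: float
    min: float
    max: float
    n_months: int

    def __post_init__(self) -> None:
        if self.n_months < 1:
            raise ValueError("summary needs at least one month")


def summarize(values: np.ndarray) -> SummaryStats:
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no evaluable months in window")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return SummaryStats(
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        n_months=int(vals.size),
    )


def procurement_accuracy(
    adequacy: AdequacySeries, window: MonthGrid | None = None
) -> SummaryStats:
    """Summary of the monthly percentage difference over the analysis window.

    Negative mean = under-procurement relative to the filled-to-max
    benchmark, positive = over-procurement.
    """
    series = adequacy.pct_series
    if window is not None:
        series = series.restrict(window)
    return summarize(series.values)


def inventory_to_consumption_ratio(
    filledmax: MonthlySeries, consumption: MonthlySeries
) -> tuple[MonthlySeries, SummaryStats]:
    """Filled-to-max requirement as a percentage of same-month consumption.

    Zero-consumption months have no defined ratio; they are excluded (NaN)
    and logged so the summary's n_months stays transparent. Under constant
    demand the ratio is exactly ``100 x M`` for every evaluable month.
    """
    filledmax.same_grid(consumption)
    cons = consumption.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cons > 0, 100.0 * filledmax.values / cons, np.nan)
    n_zero = int(np.sum((cons <= 0) & ~np.isnan(filledmax.values)))
    if n_zero:
        warnings.warn(
            f"{n_zero} zero-consumption months excluded from inventory-to-consumption ratio",
            stacklevel=2,
        )
    series = MonthlySeries(filledmax.grid, ratio, kind="ratio")
    return series, summarize(ratio)


def demographic_vs_dispensed(
    demographic: MonthlySeries, dispensed: MonthlySeries
) -> tuple[MonthlySeries, SummaryStats, float]:
    """Demographic consumption as a percentage of dispensed-to-client data.

    Returns the monthly ratio series, its summary, and the demographic
    forecast error: ``100 - mean`` when the mean ratio is below 100%
    (demographic estimates under-forecast), else 0.
    """
    demographic.same_grid(dispensed)
    disp = dispensed.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(disp > 0, 100.0 * demographic.values / disp, np.nan)
    if np.all(np.isnan(ratio)):
        raise ValueError("no overlapping months with positive dispensed data")
    series = MonthlySeries(demographic.grid, ratio, kind="ratio")
    summary = summarize(ratio)
    forecast_error = max(0.0, 100.0 - summary.mean)
    return series, summary, forecast_error


def validate_against_reported(
    ledger: InventoryLedger, snapshots: Sequence[tuple[str | Month, float]]
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of imputed ending balances with reported inventory.

    ``snapshots`` are (month, physically reported system inventory) pairs,
    e.g. from periodic stock counts. Returns r and the paired table used to
    compute it (for scatter plotting). At least 3 snapshot months must fall
    on the ledger grid; zero variance in either vector leaves r undefined
    (NaN).
    """
    pairs = []
    for m, reported in snapshots:
        m = month(m)
        if m in ledger.grid:
            pairs.append((m, ledger.ending[ledger.grid.offset(m)], float(reported)))
    if len(pairs) < 3:
        raise ValueError(
            f"need at least 3 snapshot months on the ledger grid, got {len(pairs)}"
        )
    table = pd.DataFrame(pairs, columns=["month", "imputed_ending", "reported"]).set_index("month")
    imputed = table["imputed_ending"].to_numpy()
    reported_v = table["reported"].to_numpy()
    if np.ptp(imputed) == 0 or np.ptp(reported_v) == 0:
        warnings.warn("zero variance in one vector; correlation undefined", stacklevel=2)
        return float("nan"), table
    r = float(stats.pearsonr(imputed, reported_v).statistic)
    return r, table
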