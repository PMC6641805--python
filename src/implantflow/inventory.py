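"""Imputed-inventory ledger, filled-to-max requirement, and their comparison.

System inventory is not observed directly; it is imputed month by month as

    ending[m] = beginning[m] + receipts[m] - consumption[m]
    beginning[m+1] = ending[m]

so over any window the ledger conserves units exactly. The benchmark is the
*filled-to-max* inventory: the stock needed to bring every supply-chain
level to its maximum months-of-stock policy. With a system total of M
months of stock, a month's filled-to-max requirement is the projected
consumption of the next M months — forward-looking, because under growing
demand the stock held today must cover tomorrow's larger offtake, not M
times today's rate. The percentage difference

    (imputed - filled_to_max) / filled_to_max

is the procurement-accuracy signal: 0% means procurement exactly matched
the system's maximum inventory need; negative is under-, positive is
over-procurement relative to that benchmark.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import Month, MonthGrid, MonthlySeries, month
from .types import ProcurementEvent, SupplyChainDesign

__all__ = [
    "InventoryLedger",
    "impute_inventory",
    "receipts_series",
    "filled_to_max",
    "pct_difference",
    "AdequacySeries",
    "truncate_analysis_window",
    "InsufficientHorizonError",
]


class InsufficientHorizonError(ValueError):
    """The series is too short to evaluate any month against the design."""


@dataclass
class InventoryLedger:
    """Per-month beginning balance, receipts, consumption, imputed ending."""

    grid: MonthGrid
    beginning: np.ndarray
    receipts: np.ndarray
    consumption: np.ndarray
    ending: np.ndarray

    @property
    def stockout_months(self) -> list[Month]:
        """Months whose imputed ending balance is negative: demand could not
        have been met from the stock the ledger says was available."""
        return [self.grid.index[i] for i in np.nonzero(self.ending < 0)[0]]

    @property
    def ending_series(self) -> MonthlySeries:
        return MonthlySeries(self.grid, self.ending.copy(), kind="inventory")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beginning": self.beginning,
                "receipts": self.receipts,
                "consumption": self.consumption,
                "ending": self.ending,
            },
            index=self.grid.index.rename("month"),
        )


def receipts_series(events: Sequence[ProcurementEvent], grid: MonthGrid) -> np.ndarray:
    """Sum shipment quantities into the grid month they arrive."""
    receipts = np.zeros(len(grid))
    for ev in events:
        if ev.arrival_month < grid.start:
            raise ValueError(
                f"shipment arriving {ev.arrival_month} predates grid start {grid.start}"
            )
        if ev.arrival_month > grid.end:
            warnings.warn(
                f"shipment arriving {ev.arrival_month} is after grid end {grid.end}; ignored",
                stacklevel=2,
            )
            continue
        receipts[grid.offset(ev.arrival_month)] += ev.quantity
    return receipts


def impute_inventory(
    beginning_balance: float,
    events: Sequence[ProcurementEvent],
    consumption: MonthlySeries,
    clamp_negative: bool = False,
) -> InventoryLedger:
    """Roll the inventory ledger forward from a beginning balance.

    Shipments are available for consumption in their arrival month. A
    negative ending balance marks a stockout month and is retained by
    default (clamping would silently break conservation and hide
    under-procurement); ``clamp_negative=True`` floors each month at zero
    for sensitivity runs.
    """
    grid = consumption.grid
    receipts = receipts_series(events, grid)
    cons = consumption.values
    n = len(grid)
    beginning = np.empty(n)
    ending = np.empty(n)
    bal = float(beginning_balance)
    for i in range(n):
        beginning[i] = bal
        bal = bal + receipts[i] - cons[i]
        if clamp_negative and bal < 0:
            bal = 0.0
        ending[i] = bal
    ledger = InventoryLedger(grid, beginning, receipts, cons.copy(), ending)
    if not clamp_negative and ledger.stockout_months:
        warnings.warn(
            f"{len(ledger.stockout_months)} stockout months (negative imputed inventory), "
            f"first at {ledger.stockout_months[0]}",
            stacklevel=2,
        )
    return ledger


def filled_to_max(
    consumption: MonthlySeries, design: SupplyChainDesign
) -> MonthlySeries:
    """Inventory required each month to fill every level to its maximum.

    With an effective system total of M months of stock, the requirement at
    month m is the projected consumption of the next M months starting at m
    (the final fractional month pro-rated linearly). Months without a full
    forward horizon are NaN — excluded rather than extrapolated. Under
    constant demand d this reduces to ``M x d``.
    """
    M = design.effective_total
    whole = math.floor(M)
    frac = M - whole
    cons = consumption.values
    n = len(cons)
    need = design.horizon_months  # ceil(M) months of forward data
    out = np.full(n, np.nan)
    for m in range(n):
        if m + need > n:
            break
        total = float(np.sum(cons[m : m + whole]))
        if frac > 0:
            total += frac * cons[m + whole]
        out[m] = total
    if np.all(np.isnan(out)):
        warnings.warn(
            f"no month has the {need} forward months the design requires; "
            "filled-to-max series is empty",
            stacklevel=2,
        )
    return MonthlySeries(consumption.grid, out, kind="inventory")


@dataclass
class AdequacySeries:
    """Month-by-month procurement adequacy.

    ``pct_difference`` is in percent (0 = accurate, negative =
    under-procurement); ``surplus_units`` is the raw imputed minus
    filled-to-max gap. Months where filled-to-max is zero or unevaluable
    are NaN and listed in ``excluded_months``.
    """

    grid: MonthGrid
    pct_difference: np.ndarray
    surplus_units: np.ndarray
    excluded_months: list[Month] = field(default_factory=list)

    @property
    def pct_series(self) -> MonthlySeries:
        return MonthlySeries(self.grid, self.pct_difference.copy(), kind="ratio")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pct_difference": self.pct_difference, "surplus_units": self.surplus_units},
            index=self.grid.index.rename("month"),
        )


def pct_difference(imputed: MonthlySeries, filledmax: MonthlySeries) -> AdequacySeries:
    """Percentage difference between imputed and filled-to-max inventory.

    ``100 x (imputed[m] - filledmax[m]) / filledmax[m]``. Zero-demand months
    (filled-to-max of 0) have no defined accuracy and are excluded.
    """
    imputed.same_grid(filledmax)
    fm = filledmax.values
    diff = imputed.values - fm
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(fm != 0, 100.0 * diff / fm, np.nan)
    pct = np.where(np.isnan(fm), np.nan, pct)
    surplus = np.where(np.isnan(fm), np.nan, diff)
    excluded = [imputed.grid.index[i] for i in np.nonzero(np.isnan(pct))[0]]
    return AdequacySeries(imputed.grid, pct, surplus, excluded)


def truncate_analysis_window(
    series: MonthlySeries,
    design: SupplyChainDesign | float,
    last_data_month: str | Month,
) -> MonthlySeries:
    """Cut a results series to the months the data can actually support.

    A month's filled-to-max benchmark needs ceil(M) months of forward
    consumption, so the analysis window ends ceil(M) months before the last
    month with data: months from the grid start through
    ``last_data_month - ceil(M)`` are retained. ``design`` may be the
    supply-chain design or a raw months-of-stock total (M = 0 leaves the
    window unchanged).
    """
    last = month(last_data_month)
    if isinstance(design, SupplyChainDesign):
        horizon = design.horizon_months
    else:
        if design < 0:
            raise ValueError("months of stock must be non-negative")
        horizon = math.ceil(float(design))
    end = last - horizon
    if end < series.grid.start:
        raise InsufficientHorizonError(
            f"window is empty: data through {last} minus {horizon} months "
            f"ends before the series start {series.grid.start}; a longer input series is needed"
        )
    return series.restrict(series.grid.subgrid(end=end))
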