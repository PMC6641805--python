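"""Contiguous monthly time grids and the series defined on them.

Every stage of the pipeline — user estimation, consumption, the inventory
ledger, adequacy ratios — is a value per calendar month on one shared grid.
Calendar months are the atomic period: a shipment arriving in a month is
available for consumption in that month, and survey observations are anchored
to their fieldwork midpoint month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Month", "MonthGrid", "MonthlySeries", "GridMismatchError", "month"]

#: A calendar year-month; pandas Period with monthly frequency.
Month = pd.Period


def month(value: str | Month) -> Month:
    """Coerce ``'YYYY-MM'`` strings (or Periods) to a monthly Period."""
    if isinstance(value, pd.Period):
        if value.freqstr.upper() not in ("M", "ME"):
            raise ValueError(f"expected monthly period, got freq {value.freqstr}")
        return value
    return pd.Period(value, freq="M")


class GridMismatchError(ValueError):
    """Raised when series defined on different month grids are combined."""


@dataclass(frozen=True)
class MonthGrid:
    """A contiguous run of calendar months.

    Parameters
    ----------
    start : Month or str
        First month of the grid (``'YYYY-MM'`` accepted).
    n_months : int
        Number of contiguous months; must be positive.
    """

    start: Month
    n_months: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", month(self.start))
        if self.n_months < 1:
            raise ValueError(f"n_months must be positive, got {self.n_months}")

    @property
    def end(self) -> Month:
        return self.start + (self.n_months - 1)

    @property
    def index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")

    def __len__(self) -> int:
        return self.n_months

    def __contains__(self, m: object) -> bool:
        try:
            m = month(m)  # type: ignore[arg-type]
        except (ValueError, TypeError):
            return False
        return self.start <= m <= self.end

    def offset(self, m: str | Month) -> int:
        """Zero-based position of ``m`` within the grid."""
        m = month(m)
        if m not in self:
            raise ValueError(f"{m} outside grid {self.start}..{self.end}")
        return (m - self.start).n

    def subgrid(self, start: str | Month | None = None, end: str | Month | None = None) -> "MonthGrid":
        """Restrict the grid to ``[start, end]`` (both inclusive, both clipped)."""
        s = self.start if start is None else max(self.start, month(start))
        e = self.end if end is None else min(self.end, month(end))
        if e < s:
            raise ValueError(f"empty grid: {s} after {e}")
        return MonthGrid(s, (e - s).n + 1)


@dataclass
class MonthlySeries:
    """One real value per month of a :class:`MonthGrid`.

    ``kind`` labels what the numbers are (``users``, ``consumption``,
    ``inventory``, ``ratio``); users must be non-negative. Consumption is
    non-negative as observed data but a demographic estimate can dip below
    zero under user decline (flagged upstream), and imputed inventory goes
    negative in a stockout month, so neither is constrained here. NaN marks
    months excluded from analysis (e.g. no forward horizon).
    """

    grid: MonthGrid
    values: np.ndarray
    kind: str = "consumption"

    _NONNEG_KINDS = frozenset({"users"})
    _KINDS = frozenset({"users", "consumption", "inventory", "ratio"})

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.grid):
            raise ValueError(
                f"values length {self.values.shape} does not match grid of {len(self.grid)} months"
            )
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.kind in self._NONNEG_KINDS and np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError(f"{self.kind} series must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MonthlySeries):
            return NotImplemented
        return (
            self.grid == other.grid
            and self.kind == other.kind
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    # -- alignment ---------------------------------------------------------
    def same_grid(self, other: "MonthlySeries") -> None:
        if self.grid != other.grid:
            raise GridMismatchError(
                f"series on different grids: {self.grid.start}x{len(self.grid)} "
                f"vs {other.grid.start}x{len(other.grid)}"
            )

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, m: str | Month) -> float:
        return float(self.values[self.grid.offset(m)])

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.grid.index, name=self.kind)

    def restrict(self, window: MonthGrid) -> "MonthlySeries":
        """Slice to a sub-window of the same calendar run."""
        i0 = self.grid.offset(window.start)
        i1 = self.grid.offset(window.end)
        return MonthlySeries(window, self.values[i0 : i1 + 1].copy(), kind=self.kind)

    @classmethod
    def constant(cls, grid: MonthGrid, value: float, kind: str = "consumption") -> "MonthlySeries":
        return cls(grid, np.full(len(grid), float(value)), kind=kind)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str | Month, float]], kind: str = "consumption"
    ) -> "MonthlySeries":
        """Build a series from (month, value) pairs covering contiguous months."""
        items = sorted(((month(m), float(v)) for m, v in pairs), key=lambda t: t[0])
        if not items:
            raise ValueError("no pairs supplied")
        months_, vals = zip(*items)
        grid = MonthGrid(months_[0], (months_[-1] - months_[0]).n + 1)
        if len(months_) != len(grid) or any(
            (b - a).n != 1 for a, b in zip(months_, months_[1:])
        ):
            missing = set(grid.index) - set(months_)
            raise ValueError(f"months are not contiguous; missing or duplicated: {sorted(missing)!r}")
        return cls(grid, np.array(vals), kind=kind)
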