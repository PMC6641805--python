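"""Scenario bundle and its on-disk CSV/YAML representation.

A scenario directory holds everything one country-model run needs:

- ``config.yaml``    — supply-chain levels and maxima, brand mix, CYPs,
  lead-time default, policy flags, grid bounds.
- ``procurement.csv``— shipment arrivals: arrival_month, quantity, brand,
  arrival_source.
- ``consumption.csv``— optional dispensed-to-client data: month,
  dispensed_units.
- ``surveys.csv``    — demographic observations: month, population_wra,
  mcpr, implant_share, implant_cpr, source_mix_public_ngo (blank cells on
  the unused parameterisation).

Fractions are stored as proportions in [0,1]; a column may instead carry
percentages by taking a ``_pct`` suffix (converted at parse time).
Validation problems are aggregated and reported together so one pass over
the files fixes them all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .demand import CYP_YEARS, CypFactors, blend_cyp
from .grids import Month, MonthGrid, MonthlySeries, month
from .types import (
    DEFAULT_LEAD_TIME_MONTHS,
    ArrivalSource,
    Brand,
    BrandMix,
    ProcurementEvent,
    SupplyChainDesign,
    SurveyPoint,
)

__all__ = ["Scenario", "ScenarioValidationError", "read_scenario", "write_scenario"]

_FRACTION_COLUMNS = {"mcpr", "implant_share", "implant_cpr", "source_mix_public_ngo"}


class ScenarioValidationError(ValueError):
    """All schema/consistency problems found in a scenario, reported together."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n  - " + "\n  - ".join(self.problems)
        )


@dataclass
class Scenario:
    """Everything one model run needs, aligned to a single month grid."""

    grid: MonthGrid
    design: SupplyChainDesign
    events: list[ProcurementEvent] = field(default_factory=list)
    dispensed: Optional[MonthlySeries] = None
    surveys: list[SurveyPoint] = field(default_factory=list)
    brand_mix: BrandMix = field(
        default_factory=lambda: BrandMix({Brand.ETONOGESTREL_1ROD: 1.0})
    )
    cyp_years: Mapping[Brand, float] = field(default_factory=lambda: dict(CYP_YEARS))
    beginning_balance: float = 0.0
    lead_time_months: int = DEFAULT_LEAD_TIME_MONTHS
    clamp_negative_inventory: bool = False
    clamp_negative_consumption: bool = False
    name: str = "scenario"

    @property
    def cyp_factors(self) -> CypFactors:
        return blend_cyp(self.brand_mix, self.cyp_years)

    @property
    def last_data_month(self) -> Month:
        """Last month with any demand signal: dispensed data or a survey."""
        candidates = []
        if self.dispensed is not None:
            candidates.append(self.dispensed.grid.end)
        if self.surveys:
            candidates.append(max(p.month for p in self.surveys))
        return max(candidates) if candidates else self.grid.end


def _depct(df: pd.DataFrame) -> pd.DataFrame:
    """Convert ``*_pct`` percentage columns to plain proportion columns."""
    out = df.copy()
    for col in list(out.columns):
        if col.endswith("_pct"):
            base = col[: -len("_pct")]
            if base in out.columns:
                raise ScenarioValidationError(
                    [f"both {col!r} and {base!r} present; supply one"]
                )
            out[base] = out[col] / 100.0
            out = out.drop(columns=[col])
    return out


def _read_consumption(path: Path, problems: list[str]) -> Optional[MonthlySeries]:
    if not path.exists():
        return None
    df = pd.read_csv(path)
    for col in ("month", "dispensed_units"):
        if col not in df.columns:
            problems.append(f"{path.name}: missing column {col!r}")
            return None
    if df["month"].duplicated().any():
        dupes = df.loc[df["month"].duplicated(), "month"].tolist()
        problems.append(f"{path.name}: duplicate month rows: {dupes}")
        return None
    if (df["dispensed_units"] < 0).any():
        bad = df.loc[df["dispensed_units"] < 0, "month"].tolist()
        problems.append(f"{path.name}: negative dispensed_units in months {bad}")
        return None
    try:
        return MonthlySeries.from_pairs(
            zip(df["month"], df["dispensed_units"]), kind="consumption"
        )
    except ValueError as exc:
        problems.append(f"{path.name}: {exc}")
        return None


def _read_procurement(path: Path, problems: list[str]) -> list[ProcurementEvent]:
    if not path.exists():
        return []
    df = pd.read_csv(path)
    needed = {"arrival_month", "quantity", "brand"}
    if missing := needed - set(df.columns):
        problems.append(f"{path.name}: missing columns {sorted(missing)}")
        return []
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                ProcurementEvent(
                    arrival_month=row["arrival_month"],
                    quantity=int(row["quantity"]),
                    brand=row["brand"],
                    arrival_source=row.get("arrival_source", "reported")
                    if not pd.isna(row.get("arrival_source", "reported"))
                    else "reported",
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"{path.name} row {i}: {exc}")
    return events


def _read_surveys(path: Path, problems: list[str]) -> list[SurveyPoint]:
    if not path.exists():
        return []
    df = _depct(pd.read_csv(path))
    if missing := {"month", "population_wra"} - set(df.columns):
        problems.append(f"{path.name}: missing columns {sorted(missing)}")
        return []
    points = []
    for i, row in df.iterrows():
        def get(col: str):
            v = row.get(col)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        try:
            points.append(
                SurveyPoint(
                    month=row["month"],
                    population_wra=float(row["population_wra"]),
                    mcpr=get("mcpr"),
                    implant_share=get("implant_share"),
                    implant_cpr=get("implant_cpr"),
                    source_mix_public_ngo=get("source_mix_public_ngo") or 1.0,
                )
            )
        except ValueError as exc:
            problems.append(f"{path.name} row {i}: {exc}")
    return points


def read_scenario(directory: str | Path) -> Scenario:
    """Load and validate a scenario directory.

    The month grid is taken from the config's ``start_month``/``n_months``
    if given, else from the consumption series, else from the span of
    survey and procurement months. All problems across the files are
    collected into one :class:`ScenarioValidationError`.
    """
    directory = Path(directory)
    problems: list[str] = []
    cfg_path = directory / "config.yaml"
    if not cfg_path.exists():
        raise ScenarioValidationError([f"missing {cfg_path}"])
    cfg = yaml.safe_load(cfg_path.read_text()) or {}

    try:
        design = SupplyChainDesign(
            levels=[(lv["name"], lv["max_months"]) for lv in cfg.get("levels", [])],
            model_total_override=cfg.get("model_total_override"),
        )
    except (ValueError, KeyError, TypeError) as exc:
        problems.append(f"config.yaml levels: {exc}")
        design = None  # type: ignore[assignment]

    try:
        brand_mix = BrandMix(cfg.get("brand_mix", {Brand.ETONOGESTREL_1ROD: 1.0}))
    except ValueError as exc:
        problems.append(f"config.yaml brand_mix: {exc}")
        brand_mix = BrandMix({Brand.ETONOGESTREL_1ROD: 1.0})
    cyp_years = {Brand(b): float(v) for b, v in cfg.get("cyp_years", {}).items()} or dict(
        CYP_YEARS
    )

    dispensed = _read_consumption(directory / "consumption.csv", problems)
    events = _read_procurement(directory / "procurement.csv", problems)
    surveys = _read_surveys(directory / "surveys.csv", problems)

    grid: Optional[MonthGrid] = None
    if "start_month" in cfg and "n_months" in cfg:
        grid = MonthGrid(cfg["start_month"], int(cfg["n_months"]))
    elif dispensed is not None:
        grid = dispensed.grid
    else:
        months = [p.month for p in surveys] + [e.arrival_month for e in events]
        if months:
            first, last = min(months), max(months)
            grid = MonthGrid(first, (last - first).n + 1)
        else:
            problems.append("cannot determine month grid: no config bounds, consumption, surveys or procurement")

    if grid is not None and dispensed is not None and dispensed.grid != grid:
        try:
            dispensed = dispensed.restrict(grid)
        except ValueError:
            problems.append(
                f"consumption.csv covers {dispensed.grid.start}..{dispensed.grid.end}, "
                f"which does not span the configured grid {grid.start}..{grid.end}"
            )
    if grid is not None:
        for ev in events:
            if ev.arrival_month < grid.start:
                problems.append(
                    f"procurement.csv: arrival {ev.arrival_month} before grid start {grid.start}"
                )
        for p in surveys:
            if p.month not in grid:
                problems.append(f"surveys.csv: month {p.month} outside grid")

    if problems:
        raise ScenarioValidationError(problems)
    assert grid is not None and design is not None

    return Scenario(
        grid=grid,
        design=design,
        events=events,
        dispensed=dispensed,
        surveys=surveys,
        brand_mix=brand_mix,
        cyp_years=cyp_years,
        beginning_balance=float(cfg.get("beginning_balance", 0.0)),
        lead_time_months=int(cfg.get("lead_time_months", DEFAULT_LEAD_TIME_MONTHS)),
        clamp_negative_inventory=bool(cfg.get("clamp_negative_inventory", False)),
        clamp_negative_consumption=bool(cfg.get("clamp_negative_consumption", False)),
        name=str(cfg.get("name", directory.name)),
    )


def write_scenario(scenario: Scenario, directory: str | Path) -> Path:
    """Write a scenario to a directory in the on-disk layout ``read_scenario``
    consumes; round-trips to an equal object."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    cfg = {
        "name": scenario.name,
        "start_month": str(scenario.grid.start),
        "n_months": int(scenario.grid.n_months),
        "levels": [{"name": n, "max_months": m} for n, m in scenario.design.levels],
        "brand_mix": {b.value: f for b, f in scenario.brand_mix.fractions.items()},
        "cyp_years": {b.value: v for b, v in scenario.cyp_years.items()},
        "beginning_balance": scenario.beginning_balance,
        "lead_time_months": scenario.lead_time_months,
        "clamp_negative_inventory": scenario.clamp_negative_inventory,
        "clamp_negative_consumption": scenario.clamp_negative_consumption,
    }
    if scenario.design.model_total_override is not None:
        cfg["model_total_override"] = scenario.design.model_total_override
    (directory / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))

    if scenario.events:
        pd.DataFrame(
            {
                "arrival_month": [str(e.arrival_month) for e in scenario.events],
                "quantity": [e.quantity for e in scenario.events],
                "brand": [e.brand.value for e in scenario.events],
                "arrival_source": [e.arrival_source.value for e in scenario.events],
            }
        ).to_csv(directory / "procurement.csv", index=False)

    if scenario.dispensed is not None:
        pd.DataFrame(
            {
                "month": scenario.dispensed.grid.index.astype(str),
                "dispensed_units": scenario.dispensed.values,
            }
        ).to_csv(directory / "consumption.csv", index=False)

    if scenario.surveys:
        pd.DataFrame(
            {
                "month": [str(p.month) for p in scenario.surveys],
                "population_wra": [p.population_wra for p in scenario.surveys],
                "mcpr": [p.mcpr for p in scenario.surveys],
                "implant_share": [p.implant_share for p in scenario.surveys],
                "implant_cpr": [p.implant_cpr for p in scenario.surveys],
                "source_mix_public_ngo": [p.source_mix_public_ngo for p in scenario.surveys],
            }
        ).to_csv(directory / "surveys.csv", index=False)

    return directory
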