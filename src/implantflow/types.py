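"""Domain objects: supply-chain design, procurement events, survey points.

The supply chain is described purely by its inventory-control policy: an
ordered list of levels (central medical stores down to service delivery
points), each with a maximum months-of-stock holding. The system total —
the months of stock needed to fill every level to its maximum — is the
single number ``M`` the inventory engine consumes. Some countries run their
model on an adjusted total (e.g. when not all product flows to the lowest
level), so an explicit override may replace the arithmetic sum.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .grids import Month, month

__all__ = [
    "Brand",
    "BrandMix",
    "SupplyChainDesign",
    "ProcurementEvent",
    "ArrivalSource",
    "SurveyPoint",
    "DEFAULT_LEAD_TIME_MONTHS",
]

#: Months from factory shipment to in-country availability when no receipt
#: date is reported; a config knob, not a constant of the model.
DEFAULT_LEAD_TIME_MONTHS = 3


class Brand(str, enum.Enum):
    """The two hormonal implant products in the market."""

    ETONOGESTREL_1ROD = "etonogestrel_1rod"  # 1-rod, 3-year (Implanon / Implanon NXT)
    LEVONORGESTREL_2ROD = "levonorgestrel_2rod"  # 2-rod, 5-year (Jadelle)


class ArrivalSource(str, enum.Enum):
    """Whether a shipment's in-country arrival month was reported or imputed
    from a shipping lead time."""

    REPORTED = "reported"
    ESTIMATED_LEAD_TIME = "estimated_lead_time"


@dataclass(frozen=True)
class BrandMix:
    """Fraction of volume per brand; fractions sum to 1."""

    fractions: Mapping[Brand, float]

    _TOL = 1e-9

    def __post_init__(self) -> None:
        fr = {Brand(b): float(f) for b, f in self.fractions.items()}
        object.__setattr__(self, "fractions", fr)
        if any(f < 0 for f in fr.values()):
            raise ValueError(f"brand fractions must be non-negative: {fr}")
        total = sum(fr.values())
        if abs(total - 1.0) > self._TOL:
            raise ValueError(f"brand fractions must sum to 1, got {total!r}")

    def __getitem__(self, brand: Brand | str) -> float:
        return self.fractions.get(Brand(brand), 0.0)


@dataclass(frozen=True)
class SupplyChainDesign:
    """Ordered supply-chain levels with their maximum months-of-stock policy.

    Parameters
    ----------
    levels : sequence of (name, max_months)
        Top of the chain first; ``max_months`` is a positive real (months of
        stock may be fractional).
    model_total_override : float, optional
        Replaces the arithmetic system total where the modelled total
        deviates from the design-on-paper total.
    """

    levels: Sequence[tuple[str, float]]
    model_total_override: Optional[float] = None

    def __post_init__(self) -> None:
        lv = tuple((str(n), float(m)) for n, m in self.levels)
        object.__setattr__(self, "levels", lv)
        if not lv:
            raise ValueError("a supply chain needs at least one level")
        if any(m <= 0 for _, m in lv):
            raise ValueError(f"level maxima must be positive: {lv}")
        if self.model_total_override is not None and self.model_total_override <= 0:
            raise ValueError("model_total_override must be positive")

    @property
    def system_total(self) -> float:
        """Sum of level maxima: months of stock to fill every level to max."""
        return float(sum(m for _, m in self.levels))

    @property
    def effective_total(self) -> float:
        """The months-of-stock total the model actually uses (``M``)."""
        if self.model_total_override is not None:
            return float(self.model_total_override)
        return self.system_total

    @property
    def horizon_months(self) -> int:
        """Whole months of forward consumption needed to evaluate one month."""
        return math.ceil(self.effective_total)


@dataclass(frozen=True)
class ProcurementEvent:
    """One shipment arriving in-country.

    The arrival month is when the quantity becomes available to the system;
    if only the factory ship date is known the arrival is imputed by adding
    the country lead time and tagged ``estimated_lead_time``.
    """

    arrival_month: Month
    quantity: int
    brand: Brand
    arrival_source: ArrivalSource = ArrivalSource.REPORTED

    def __post_init__(self) -> None:
        object.__setattr__(self, "arrival_month", month(self.arrival_month))
        object.__setattr__(self, "brand", Brand(self.brand))
        object.__setattr__(self, "arrival_source", ArrivalSource(self.arrival_source))
        if self.quantity < 0:
            raise ValueError(f"shipment quantity must be non-negative, got {self.quantity}")

    @classmethod
    def from_ship_month(
        cls,
        ship_month: str | Month,
        quantity: int,
        brand: Brand | str,
        lead_time_months: int = DEFAULT_LEAD_TIME_MONTHS,
    ) -> "ProcurementEvent":
        """Impute the in-country arrival from a factory ship date."""
        return cls(
            month(ship_month) + int(lead_time_months),
            quantity,
            Brand(brand),
            ArrivalSource.ESTIMATED_LEAD_TIME,
        )


@dataclass(frozen=True)
class SurveyPoint:
    """One demographic observation anchored at the survey fieldwork midpoint.

    Either ``mcpr`` together with ``implant_share`` (implants' share of the
    method mix), or the pre-multiplied ``implant_cpr``, must be supplied —
    exactly one of the two parameterisations. ``source_mix_public_ngo`` is
    the fraction of implant users served through public and NGO channels
    (private retail users fall outside the modelled supply chain).
    """

    month: Month
    population_wra: float
    mcpr: Optional[float] = None
    implant_share: Optional[float] = None
    implant_cpr: Optional[float] = None
    source_mix_public_ngo: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "month", month(self.month))
        has_pair = self.mcpr is not None and self.implant_share is not None
        has_cpr = self.implant_cpr is not None
        if has_cpr and (self.mcpr is not None or self.implant_share is not None):
            raise ValueError(
                f"survey {self.month}: supply either (mcpr & implant_share) or implant_cpr, not both"
            )
        if not has_pair and not has_cpr:
            raise ValueError(
                f"survey {self.month}: needs mcpr & implant_share, or implant_cpr"
            )
        if self.population_wra < 0:
            raise ValueError(f"survey {self.month}: population_wra must be non-negative")
        for name in ("mcpr", "implant_share", "implant_cpr", "source_mix_public_ngo"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"survey {self.month}: {name}={v} outside [0, 1]")

    @property
    def effective_implant_cpr(self) -> float:
        """Implant prevalence among women of reproductive age, whichever
        parameterisation was supplied."""
        if self.implant_cpr is not None:
            return float(self.implant_cpr)
        return float(self.mcpr) * float(self.implant_share)  # type: ignore[arg-type]
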