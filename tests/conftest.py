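import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from implantflow import (
    Brand,
    BrandMix,
    MonthGrid,
    MonthlySeries,
    SupplyChainDesign,
)


@pytest.fixture
def grid24() -> MonthGrid:
    return MonthGrid("2010-01", 24)


@pytest.fixture
def design18() -> SupplyChainDesign:
    """The five-level worked-example system totalling 18 months of stock."""
    return SupplyChainDesign(
        levels=[("central", 5), ("regional", 4), ("district", 4), ("sdp", 4), ("chw", 1)]
    )


@pytest.fixture
def mix_75_25() -> BrandMix:
    return BrandMix({Brand.ETONOGESTREL_1ROD: 0.75, Brand.LEVONORGESTREL_2ROD: 0.25})


def constant_series(grid: MonthGrid, value: float, kind: str = "consumption") -> MonthlySeries:
    return MonthlySeries(grid, np.full(len(grid), float(value)), kind=kind)
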