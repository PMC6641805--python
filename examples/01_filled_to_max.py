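"""How much inventory does a supply chain need to be 'full'?

A five-level supply chain (central 5 + regional 4 + district 4 + SDP 4 +
community health worker 1) holds 18 months of stock when every level is at
its maximum. The filled-to-max requirement at a month is the projected
consumption of the next 18 months — so under growing demand it is larger
than 18x the current monthly rate.
"""

import numpy as np

from implantflow import MonthGrid, MonthlySeries, SupplyChainDesign, filled_to_max

design = SupplyChainDesign(
    levels=[("central", 5), ("regional", 4), ("district", 4), ("sdp", 4), ("chw", 1)]
)
print(f"system total: {design.system_total:.0f} months of stock")

grid = MonthGrid("2010-01", 18)

flat = MonthlySeries.constant(grid, 15_000)
fm_flat = filled_to_max(flat, design)
print(f"constant 15,000/month  -> {fm_flat.values[0]:>9,.0f} units to fill the system")

growing = MonthlySeries(grid, np.linspace(15_000, 26_250, 18))
fm_grow = filled_to_max(growing, design)
print(f"demand +75% over 18 mo -> {fm_grow.values[0]:>9,.0f} units "
      f"(~{round(fm_grow.values[0], -4):,.0f})")
print(f"growth premium         -> {fm_grow.values[0] - fm_flat.values[0]:>9,.0f} units")
# The premium is the extra stock that must already be in the pipeline today
# to cover the larger offtake of the coming months.
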