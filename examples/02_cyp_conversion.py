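"""From demographic survey rates to monthly device consumption.

Implant users are estimated as population x mCPR x implant share of method
mix x public/NGO source mix, then converted to devices through couple-years
of protection (CYP): one device protects for 2.5 years (etonogestrel 1-rod)
or 3.8 years (levonorgestrel 2-rod), so a steady user base of N needs
N / CYP devices a year just for replacement, plus one device per net new
user.
"""

import numpy as np

from implantflow import (
    Brand, BrandMix, MonthGrid, MonthlySeries,
    blend_cyp, estimate_users, users_to_products_annual, users_to_products_monthly,
)

mix = BrandMix({Brand.LEVONORGESTREL_2ROD: 0.25, Brand.ETONOGESTREL_1ROD: 0.75})
cf = blend_cyp(mix)
print(f"blended CYP (25/75 levo/eto): {cf.blended_cyp} years/device")
print(f"annual conversion factor:     {cf.annual_cf:.3f} devices per user-year")
print(f"replacement interval:         {cf.months_of_protection:.1f} months")

grid = MonthGrid("2015-01", 13)
users = estimate_users(
    MonthlySeries.constant(grid, 1_000_000, "users"),
    mcpr=MonthlySeries.constant(grid, 0.20, "ratio"),
    implant_share=MonthlySeries.constant(grid, 0.10, "ratio"),
)
print(f"\nusers (1M WRA, mCPR 20%, implant share 10%): {users.values[0]:,.0f}")

monthly = users_to_products_monthly(users, cf)
annual = users_to_products_annual(users.values[0], users.values[0], cf)
print(f"steady-state consumption: {monthly.values[0]:,.1f} devices/month "
      f"({annual:,.0f}/year — replacement only, no growth term)")
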