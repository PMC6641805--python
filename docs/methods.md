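# Methods

This note records the modelling conventions, parameter choices and known
limitations behind `implantflow`, in the spirit of a model-description
vignette.

## Time base and units

Calendar months are the atomic period. Every series (users, consumption,
inventory, ratios) lives on one contiguous `MonthGrid`; cross-grid
arithmetic is rejected rather than silently aligned. A shipment is
available for consumption in its arrival month — within-month ordering is
not modelled, and treating arrivals as start-of-month is the documented
convention. When only a factory ship date is known, the in-country arrival
is imputed as ship month + lead time (default 3 months, a config knob).
An unknown beginning balance defaults to 0 units, appropriate for a newly
introduced method whose pre-scale-up stocks were negligible.

Quantities are devices ("units"); inventory-control parameters are months
of stock, i.e. stock relative to monthly consumption.

## Imputed inventory

The ledger is a pure accounting identity: ending = beginning + receipts −
consumption, with each month's ending carried into the next. Conservation
is exact in the arithmetic of the inputs (integer inputs give integer
balances). Negative endings are *retained* and flagged as stockout months:
clamping at zero would hide under-procurement and break conservation. A
`clamp_negative` option exists for sensitivity runs; it changes the
meaning of the ledger and is off everywhere by default.

## Filled-to-max inventory

The requirement at month m is **forward-looking**: the sum of projected
consumption over the next ⌈M⌉ months starting at m, with a fractional
final month pro-rated linearly (months of stock may be fractional even
though typical policies are integers). The alternative reading — current
monthly rate × M — is wrong under growth: it cannot produce the ~100,000
extra units the 18-month worked example requires when demand rises 75%.
Months lacking the full forward horizon are excluded (NaN), never
extrapolated; if no month qualifies the series is empty with a warning.

The benchmark is the system **maximum**. Whether imputed stock also
cleared minimum-level policies is a different question and out of scope,
as is allocating inventory across individual levels.

## Analysis window

Reported statistics cover grid start through the last data month minus
⌈M⌉ months, so every included month is benchmarked on actual rather than
extrapolated demand. The truncation is deliberately one month more
conservative than raw evaluability of the forward sum. For series too
short for the rule (like the 18-month worked example) the pipeline falls
back to the months with a defined benchmark and records a warning in the
run report.

## Demographic demand estimation

Survey rates are anchored at fieldwork **midpoint** months (an input
column, not computed) and linearly interpolated between points;
outside the observed range they are **held flat** — extending an uptake
trend beyond the last survey would manufacture demand the data do not
support. Interpolation is `numpy.interp`, whose end-behaviour is exactly
this flat hold.

Users convert to devices with the standard annual conversion
`(UY2 − UY1) + UY1 × CYP_CF` and its monthly adaptation
`(UM2 − UM1) + UM1 × CYP_CF/12`. Two conventions are worth stating:

- The replacement term of the monthly formula uses the **current month's**
  user base. This is the only reading that makes the monthly series
  well-defined month by month and reproduces the brand replacement
  intervals (30 months for a 2.5-year CYP, 45.6 for 3.8).
- Aggregated over a year the monthly form reproduces the annual form when
  the yearly user bases UY1/UY2 are read as within-year means; for a
  trajectory linear within the year this equivalence is exact, and the
  test suite asserts it at 1e-9 relative tolerance. The annual formula
  itself does not pin down UY for a varying trajectory; the within-year
  mean is this package's choice.

The last month of a user series has no successor; its growth term uses a
flat hold (zero growth). Months of user decline can yield negative device
requirements; they are retained and flagged (a clamp option exists)
because zeroing them would overstate cumulative demand downstream. Note
the total-products monotonicity one might expect from "more users, more
devices" holds for growing programmes; under decline the (negative) growth
term can dominate, which is precisely why such months are flagged.

Brand CYPs are blended **before** inverting: blended_cyp = Σ mix_b ×
CYP_b, conversion factor 1/blended_cyp. Blending the factors directly
would misweight the shorter-lived brand. Private retail users are outside
the modelled public/NGO channels and excluded via the source-mix factor.

All internal arithmetic is full precision; rounding (e.g. to the nearest
10,000 units for headline figures) happens only at reporting time.

## Adequacy statistics

Percentage difference, inventory-to-consumption ratio and
demographic-vs-dispensed ratio are per-month divisions; months with a zero
denominator are excluded and logged so `n_months` in every summary is
transparent. Summaries are mean, sample SD (ddof=1), min, max. The
validation statistic is the standard sample Pearson correlation (via
`scipy.stats.pearsonr`) between imputed ending balances and reported
inventory at snapshot months; no significance testing is attached, and at
least three paired months are required.

## Synthetic scenario generator

The generator exists because the real inputs to this kind of analysis —
logistics-system extracts and procurement databases — are confidential.
Its default spec is one fixed picture of a rapid-uptake country, chosen
once: 96 months from 2010-01; 8,000,000 women of reproductive age growing
2.8%/year; mCPR 15%→28% and implant share of method mix 5%→22%, both along
a logistic (steepness 8) so uptake is slow–fast–slow; public/NGO source
mix 0.9; brand mix 75/25 etonogestrel/levonorgestrel; the five-level
18-months-of-stock design; surveys at months 12 and 48 (three years
apart); shipments every 6 months sized to the next interval's dispensed
demand. These mirror a setting where consumption roughly doubles over a
few years, demand rises ~75% across an 18-month stretch of the scale-up,
and data arrive as sparse surveys plus lumpy shipments.

True monthly rates generate true users, and true consumption follows by
the same CYP chain the estimator uses — so noiseless monthly surveys
recover true consumption exactly (the recovery property). Observables
degrade the truth:

- dispensed counts = true consumption × multiplicative log-normal noise
  with mean 1 and coefficient of variation `dispensed_noise_cv` (default
  0.05; log-normal keeps counts positive), rounded to whole devices;
- surveys sample the true rates at the survey months (optional log-normal
  noise, default none);
- procurement follows a policy: `fixed_schedule` (cover the next
  interval), `noisy` (the same with log-normal quantity noise, cv 0.2), or
  `fill_to_max_exact`, which sets each month's receipt so the ending
  balance equals the filled-to-max requirement — a self-consistency
  construction under which the percentage difference is exactly 0% over
  the evaluable window. If projected demand ever fell faster than one
  month's consumption that policy would need a negative receipt; receipts
  are floored at zero in that case, which the default parameters never
  trigger. All randomness flows from one `numpy` generator seeded per
  scenario; no global state.

What the generator does **not** emulate: reporting gaps and misreporting
in dispensed data, per-level stock movements and lead-time stochasticity,
seasonality, brand-specific demand, wastage/training losses. Passing tests
therefore demonstrate correctness of the accounting and estimation
machinery under known ground truth, not calibration to any real country.

## Numerical choices and degenerate inputs

- Fractions are proportions in [0,1]; CSV columns may carry percentages
  via a `_pct` suffix, converted at parse time.
- Duplicate survey months, months outside the grid, non-contiguous
  consumption months, and mixed mCPR/implant-CPR parameterisations in one
  row are hard errors, aggregated per file so one pass fixes all.
- A single survey point degrades to constant series with a warning.
- Zero-variance validation vectors return an undefined (NaN) correlation
  rather than an arbitrary value.
- Integer-valued inputs keep ledger identities exact; comparisons in the
  test suite use exact equality where the arithmetic is exact and 1e-9
  tolerances where interpolation or blending is involved.

## Problem sizes

Default test and example runs use 96-month scenarios (500 months for the
noise-averaging property), 20-replicate randomized suites for the ledger
and closed-form properties, and 18-month grids for the worked examples;
the full suite completes in a few seconds.

## Known limitations

- The CYP replacement model treats discontinuation implicitly (CYPs are
  shorter than device efficacy); it cannot represent cohort effects such
  as a removal wave after a procurement spike.
- The filled-to-max benchmark assumes no resource constraints and that
  stock flows down-chain as designed; it is an upper inventory benchmark,
  not a forecast of feasible procurement.
- Demographic estimates inherit every bias of the surveys (sampling error,
  midpoint dating) and of the CYP factors themselves; the
  demographic-vs-dispensed ratio quantifies, but does not explain, the
  gap.
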