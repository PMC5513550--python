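# Methods

## Model overview

The package implements a Compare Locations ecoclimatic model: a
semi-mechanistic description of how a poikilotherm population grows in
favourable seasons and declines in stressful ones, driven entirely by
long-term monthly climate normals.  One location is one independent model
run; there is no dispersal, no inter-annual variability and no fitting —
the parameter presets are shipped as published and the engine is a
deterministic function of (climate, parameters, scenario).

The pipeline per location:

1. **Weekly expansion.**  Monthly normals (tmin, tmax, precipitation, RH at
   09h00 and 15h00) are expanded to a 364-day year of 52 seven-day weeks
   and 12 equal months.  Temperatures and humidity are interpolated
   piecewise-linearly from month midpoints to week midpoints with periodic
   Dec→Jan wrap; precipitation is treated as a piecewise-constant daily
   rate per month and integrated over each week, so the annual total is
   conserved exactly.  Weekly RH is the mean of the interpolated 09h00 and
   15h00 values.  Weekly mean temperature is (tmin + tmax)/2.
2. **Irrigation scenario.**  The top-up scenario raises weekly rainfall to
   at least `7 × rate` mm/week (default rate 2.5 mm/day) during the local
   summer half-year: weeks 18–44 in the northern hemisphere, weeks 1–17
   and 45–52 in the southern (sites within 1° of the equator follow the
   northern convention).  Top-up means a floor, not an addition: wet weeks
   are unchanged, so irrigation is never double-counted.
3. **Soil moisture.**  A 100 mm single-bucket store expressed as a
   dimensionless fraction of field capacity.  Weekly update:
   `sm_w = clamp(sm_{w-1} + (P_w − Ea_w)/capacity, 0, sm_cap)` with
   soil-limited actual evapotranspiration `Ea_w = Ep_w · min(1, sm_{w-1})`.
   The store may exceed 1 (supersaturation) up to `sm_cap = 5` so that
   high wet-stress thresholds (e.g. 2.5) are reachable; excess beyond the
   cap is discarded as runoff.  The year is cycled with carried-over final
   moisture until the trajectory is annually periodic (uniform-norm change
   < 1e-6, at most 100 cycles), which makes the reported series
   independent of the initial store.
4. **Growth indices.**  TI_W and MI_W are trapezoids over (DV0..DV3) and
   (SM0..SM3): zero at or below the lower threshold, linear to 1 at the
   lower optimum, 1 across the optimal band, linear to zero at the upper
   threshold.  GI_W = TI_W · MI_W; GI_A = 100 · mean(GI_W).
5. **Stress indices.**  Each mechanism produces a weekly exceedance
   (cold: shortfall of weekly degree-days above DVCS below DTCS; heat:
   tavg − TTHS; dry: SMDS − sm; wet: sm − SMWS; hot-wet: binary indicator
   of tavg > TTHW and sm > MTHW) and accumulates
   `100 · min(1, Σ_w |rate| · exceedance_w · n_w)` where `n_w` counts
   consecutive stressed weeks ending at week w.
6. **Ecoclimatic Index.**  `EI = GI_A · Π(1 − SI_i/100)` over the five
   active stresses, forced to 0 when the annual degree-day sum above DV0
   is below PDD.  Classification rounds EI half-up to an integer and
   applies the conventional 0 / 1–4 / 5–9 / 10–29 / 30–100 scheme.

Gridded runs evaluate every cell under the natural and the irrigated
scenario and compose them with a boolean irrigation mask (irrigated cells
take the irrigated EI); the composite invariant is enforced at
construction and preserved by the CSV round-trip.  `RiskGrid.to_xarray()`
provides a georeferenced in-memory dataset for regular grids.

## Parameters

All symbols live in `ParameterSet` with the published signs (cold and dry
accumulation rates are negative; the engine uses magnitudes).  The
`current` preset: DV0 = DVCS = 6.5 °C, DV1 = 18, DV2 = 26, DV3 = 33 °C;
SM0 = 0.2, SM1 = 0.6, SM2 = 1.5, SM3 = 2.5; DTCS = 10 °C-days/week,
DHCS = −0.00016 wk⁻¹; TTHS = 33 °C, THHS = 0.0035 wk⁻¹; SMDS = 0.2,
HDS = −0.008 wk⁻¹; wet stress disabled (SMWS = HWS = 0); TTHW = 22 °C,
MTHW = 0.4, PHW = 0.009 wk⁻¹; PDD = 350 °C-days.  A zero rate disables a
mechanism outright (it is not a zero threshold with positive rate).
Hydrological tunables: bucket capacity 100 mm, `sm_cap` 5, ET coefficient
`k_et` 0.6 mm day⁻¹ °C⁻¹, spin-up tolerance 1e-6 and cycle cap 100,
irrigation rate 2.5 mm/day — all exposed as function arguments.

## Numerical and design choices

Several internals of the original modelling package are proprietary or
unpublished; where the literature is silent this package makes an explicit
choice and documents it:

- **Evaporative demand** is a deliberate stand-in:
  `Ep = 7 · k_et · max(0, tavg) · (1 − rh)` mm/week.  It is zero at or
  below freezing, decreasing in humidity, and linear in temperature; no
  radiation or wind terms are attempted because monthly normals cannot
  support them.  `k_et` is exposed so sensitivity can be probed.
- **Monthly→weekly interpolation** is linear-periodic on month midpoints;
  the original's scheme is unstated.  Interpolated weekly values never
  leave the envelope of the bracketing monthly values, and precipitation
  mass is conserved exactly by construction.
- **Stress accumulation** compounds with persistence
  (`rate × exceedance × consecutive-week run length`, annual sum capped),
  with runs wrapping across the Dec→Jan boundary so southern-hemisphere
  summers are not split in two.  When every week is stressed the year is a
  single unbroken run and the plain cumulative count applies.  Published
  thresholds are strict (no stress exactly at the threshold), which makes
  each threshold the exact supremum of the zero-stress region — the only
  stress facts the sources print.
- **Hot-wet stress** uses a binary joint-condition indicator rather than a
  product of exceedance magnitudes: the mechanism proxies biotic pressure
  that builds with the duration of hot-wet conditions, and the binary form
  is the weakest assumption that preserves the published thresholds.  The
  choice changes accumulation speed, not the zero/non-zero boundary.
- **The degree-day requirement is a hard gate** (EI = 0 below PDD) rather
  than a growth modifier, treating it as a distribution limit.
- **TI_W uses the weekly mean temperature**; no diurnal-cycle integration
  is attempted.  Day-length and diapause terms are excluded (no
  parameters exist for them in any preset).
- **Classification rounds half-up** so the integer class boundaries apply
  cleanly to real-valued EI; EI rounding to 0 is unsuitable, and the
  presence criterion `is_suitable` is rounded EI ≥ 1.
- The cold-dry, cold-wet and hot-dry interaction stresses are structurally
  present in `StressResult` but carry no parameters in any preset and are
  always zero.
- The irrigation mask is boolean; no irrigation-intensity threshold is
  modelled.

## Synthetic climates

The generator emulates the *structure* of gridded monthly normals
(CliMond-like variable set) for five contrasting archetypes, so every
stage of the pipeline can be exercised without any data download.
Monthly temperature is sinusoidal (peak late January or late July by
hemisphere, with per-profile phase offsets); precipitation seasonality is
a cosine weighting; RH has a small annual cycle with its driest month set
per profile.  All randomness flows through `numpy.random.default_rng`
seeded from the caller's seed, so every site is reproducible.  Profile
contracts are asserted after generation, with bounded retries on fresh
jitter; an unsatisfiable contract raises an error naming the violation.

The `patagonia_xeric` profile is calibrated (mean 9.4 °C, amplitude
10.3 °C, ~52 mm/year winter-peaked precipitation, RH 0.30–0.80 with
driest air in late spring) so that under natural rainfall the
growing-season store stays below SM0 = 0.2 — hence GI_W ≡ 0 — while the
2.5 mm/day summer top-up produces a growth pulse peaking in weeks 9–13
(March).  Its annual precipitation is drier than the real Patagonian
steppe (~150–250 mm): the linear ET stand-in is weak in the cold season,
so a steppe-realistic winter rainfall would leave spring soil moisture
above SM0 into the growing season.  The profile trades rainfall realism
for the hydrological *behaviour* that defines the archetype (a store that
is dry whenever the site is warm enough to grow).  Passing tests on these
archetypes therefore demonstrate the engine's threshold logic and the
irrigation mechanism, not fidelity to any real station series; real-data
features such as spatial autocorrelation, inter-annual variability and
observed covariance between temperature, rainfall and humidity are not
emulated.

The synthetic grid spans cold-to-tropical means with latitude and
hyper-arid-to-wet annual totals (120–2400 mm) with longitude, with an
irrigated contiguous patch in the temperate arid sector — the situation in
which composite risk mapping is informative.

## Problem sizes

All computations are desk-scale: single-location runs are 52-week vectors
with an O(100)-cycle spin-up, threshold sweeps use 0.01 °C / 0.001
moisture grids (≤ ~2000 points), the property suites use a few hundred
random series and grids up to 10×10 cells.  The full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

- The hydrology beyond "100 mm single bucket" (ET, runoff, snow) is a
  documented stand-in, not a calibrated scheme; absolute soil-moisture
  values should not be compared against field measurements.
- Weekly-mean temperature responses understate diurnal extremes; a site
  with hot afternoons but mild weekly means accrues no heat stress.
- The accumulation law reproduces published threshold locations exactly,
  but absolute stress magnitudes between 0 and 100 depend on the chosen
  persistence weighting and are comparable only within this package.
- Suitability classes are a reporting convention; class boundaries carry
  no mechanistic meaning.
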