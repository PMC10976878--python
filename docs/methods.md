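# Methods

`rxsmoke` compares the air-quality and short-term health burden of a
year of wildfires against counterfactual scenarios in which the same
burned area burns under prescribed-fire conditions. The pipeline has
five scientific stages; each is summarized below together with its
assumptions, tunable parameters and known limits.

## Emission inventory

Per fire-day record, emissions of species *s* are

    E_s = sum_FT  BA · FC_FT · EF_{s,FT}

with burned area BA (km²), consumption FC (kg/km²) per fuel category
and emission factor EF (g/kg). The shipped factor table covers PM2.5:
short-term flaming-and-smoldering (STFS) factors of 17.57 g/kg for
western forest under prescribed (Rx) conditions, 23.2 g/kg for forest
wildfire, 7.06 g/kg for shrubland and 8.51 g/kg for grassland, plus
residual smoldering combustion (RSC) factors of 33 g/kg for woody
debris and 35.3 g/kg for duff. The CSV schema accepts other species
(CO, CO₂) if factors are supplied.

Fuel beds carry loadings in five categories (canopy, shrub, nonwoody,
woody, duff). Cover type is the largest of the canopy+woody, shrub and
nonwoody mass shares (duff excluded), mapping to forest, shrubland and
grassland respectively; ties break forest > shrubland > grassland.

Consumption is a deliberately small parameterization rather than a full
fuel-consumption model:

* canopy: 50 % consumed in wildfires, 0 % in prescribed burns;
* shrub: 50 % blackened (and consumed) in both fire types;
* surface fuels (nonwoody, woody, duff): a consumed fraction falling
  linearly from 0.9 at fuel moisture 0 to 0.3 at fuel moisture 1;
* fuel moisture is a linear, monotone map of soil moisture onto
  [0.05, 0.40] (both endpoints configurable);
* 30 % of consumed woody mass and 100 % of consumed duff are routed to
  RSC factors (configurable; field estimates for these splits vary).

This preserves the two effects the comparison hinges on — the canopy
difference between fire types and the moisture dependence of surface
consumption — without reproducing any particular consumption model's
internals. Consumption never exceeds loading and is non-increasing in
moisture, both property-tested.

## Prescribed-burn scheduling

Candidate burn days lie in March–May or September–November. The strict
burn window requires 20-ft wind speed < 5.36 m/s (12 mph), temperature
< 29.5 °C (85 °F), relative humidity in [0.25, 0.45] and soil moisture
in [0.15, 0.30] m³/m³ in the fire's grid cell. Among passing days the
minimum-wind day is chosen (escape-risk logic); wind ties break to the
earliest date — the tie-break is a package choice, documented and
deterministic. If no day passes, a fallback tier relaxes only wind
(< 15 mph) and the RH upper bound (0.6); temperature and soil-moisture
bounds and the RH lower bound are retained, since only wind and
humidity relaxations are part of the stated fallback. A fire with no
fallback day raises an error rather than silently burning on its
original date.

Multi-day events confined to one grid cell collapse to a single record
on one day; events spanning cells schedule each cell independently.
Total burned area is conserved exactly in every mode.

Rx2 additionally removes a "no burn" calendar before filtering. The
general mechanism is `screen_high_exposure_days`: for every candidate
day, forecast the population-weighted concentration if all fires
released a unit emission that day (single-day transport under that
day's winds) and exclude days above a quantile (default 0.9) of the
forecast distribution. A fixed 2012-style preset calendar
(Apr 27–May 2, May 28–Jun 2, Oct 26–28, Nov 2–5) ships as a
convenience.

## Transport surrogate

The dispersion kernel is explicitly a surrogate, not a chemical
transport model: daily emitted mass is diluted into a column of
cell area × mixing depth, advected semi-Lagrangian along the daily
cell wind, spread by a Gaussian, and carried forward with first-order
decay. Boundaries are open (mass leaving the grid is lost). Fresh
emissions travel half the daily displacement with half the Gaussian
length, approximating the emission-day average of a continuous release;
with zero wind and zero diffusion the day-one concentration reduces
exactly to the box-dilution closed form mass/(area·depth), which the
tests pin to machine precision.

Parameters (defaults): diffusion length 20 km/day; decay e-folding time
2 days (net deposition at regional scale); advection scale 0.3 of the
cell wind (transport-level winds and plume meander differ from the
near-surface layer — the value is an order-of-magnitude choice that
keeps plumes inside a ~250 km domain for about a day); mixing depth
3000 m for wildfire plumes and 1300 m for prescribed burns, following
observed plume-top heights. The depth difference means a prescribed
burn produces 3000/1300 ≈ 2.3× the surface concentration of a wildfire
per unit emission — so prescribed scenarios can approach or exceed
wildfire exposure despite emitting less, which is the behaviour the
scenario contrast is designed to probe.

The surrogate is linear in emissions and non-negative; the no-fire
scenario is therefore implicit (zero emissions give identically zero
increments) and with/without-fire differencing is exact by
construction. The surrogate makes no claim to reproduce real
concentration magnitudes; it exists so the exposure and scheduling
machinery can be exercised and tested.

## Exposure and mortality

Population-weighted exposure is PW = Σ P_i C_i / Σ P_i. Daily excess
mortality uses RR_i = exp(γ·ΔC_i) with γ = 0.00101 per µg/m³
(95 % CI 0.001001–0.001020, a fire-specific concentration–response
slope), and

    M = Σ_i P_i · I_daily · (RR_i − 1)/RR_i ,

with I_daily the baseline rate 813 per 100 000 per year divided by 365.
(RR−1)/RR is the attributable fraction; the delta-method form
M = Σ P·I·(RR−1) is available via `HealthParams(af_form="rr_minus_1")`
because published implementations of this risk function differ in which
form they use — for γ·ΔC ≪ 1 the two agree to first order, and the
small-Δ linearization M ≈ Σ P·I·γ·ΔC is property-tested at 1 %. CI
bounds come from evaluating the chain at the γ interval endpoints.
Exposure is weighted equally across people; no age structure, morbidity
or avoidance behaviour is modelled.

## Evaluation statistics

For model-observation comparison the package implements the symmetric
normalized factors of Yu et al. (2006): NMBF = M̄/Ō − 1 when M̄ ≥ Ō,
else 1 − Ō/M̄, and NMAEF = Σ|M−O| normalized by n·Ō or n·M̄ with the
same branch rule, plus Pearson r with pairwise deletion of missing
observations. Stations map to the nearest grid-cell centre (ties to the
lower row, then column index). Station-level statistics are averaged
with equal weights; an all-pairs pooled row is also reported.

## Synthetic inputs

All inputs are generated, seeded and deterministic; the generators
emulate the *structure* real data sources would provide, not their
climatology:

* Meteorology: per-season Gaussian fields (means/sds configurable) with
  spatial Gaussian smoothing (length 2 cells), truncated to physical
  ranges. Defaults make spring/fall mild and moist enough that ~40–60 %
  of cell-days pass the strict burn window, while summer (hot, RH
  ~0.15, soil moisture ~0.08) passes < 1 %. Transport direction is a
  seasonal mean plus noise, so wildfire-season and burn-season
  transport differ.
* Fires: monthly ignition weights concentrated May–September; lognormal
  sizes with mean 1.4 km² (140 ha) and σ_log = 1.5, giving the heavy
  right tail regional burned-area records show; events above 20 km²
  span consecutive days and sometimes two adjacent cells. Placement is
  uniform over the grid — no real spatial fire climatology is implied.
* Population: a mixture of Gaussian clusters (4 clusters, dispersion
  2 cells by default); a multinomial draw conserves the configured
  total exactly.
* Fuel beds: each cell draws a dominant cover type
  (forest/shrubland/grassland at 0.5/0.3/0.2) and Dirichlet category
  shares scaled by a lognormal total loading (mean 2×10⁶ kg/km²,
  roughly the order implied by ~10⁶ kg/km² consumed in forest fires).

Because the inputs are synthetic, passing tests demonstrate the
*mechanics* — conservation, filter correctness, closed-form transport
limits, risk arithmetic, directional scenario contrasts — not agreement
with any observed emission total, concentration or death count. Default
study sizes (20×20 cells at 12 km, 200 fires, one 365-day year) keep a
full comparison under a few seconds on one core.

## Numerical and I/O choices

Percent reductions in the comparison table are rounded half-up to
integers. Division guards report undefined reductions (zero baseline)
as n/a. The 365-day non-leap calendar indexes days 1–365; dates are
day-of-year. Gridded fields are written as classic NetCDF via xarray's
scipy backend with plain projected x/y km coordinates (no CRS
metadata); tables are CSV; configs TOML or YAML. Randomness uses
numpy `default_rng` seeded per generator stream, so generator outputs
are independent of call order and bit-identical across runs.

## Known limitations

No combustion chemistry or secondary aerosol, no plume rise dynamics,
no meteorological feedback, no long-range transport beyond the open
boundary, no escape-risk or crew-availability constraints on
scheduling, and no multi-year planning. The consumption scheme is a
two-parameter stand-in; users with a calibrated consumption model can
inject its output via the `ConsumptionResult` interface.
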