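# Methods

This note documents the model equations, the parameter choices that
matter, what the synthetic weather generator does and does not emulate,
and the known limitations. Units: depths and fluxes in mm, biomass in
g m⁻², temperatures in °C, thermal time in °Cd.

## Soil water balance

The profile is a cascade of seven layers (surface first). For each layer:
`0 < LL < DUL < SAT < 1` (volumetric). State is the per-layer water
content plus a surface pond.

* **Infiltration.** The day's rain + irrigation plus any carried pond
  fills layers top-down to SAT. Remaining surface water ponds up to the
  bund height (100 mm); only the excess above the bund leaves as runoff.
  Ponded water infiltrates on subsequent days before any new runoff forms.
* **Drainage.** After infiltration, each layer sheds
  `SWCON × (θ − DUL) × Δz` to the layer below (water arriving above SAT
  bypasses instantaneously). Flux out of the bottom layer (180 cm) is deep
  drainage. There is no upward flow: capillary rise is outside the scope
  of a cascading model, which matters most for the clay loam under dry
  topsoil.
* **Soil evaporation** (Ritchie two-stage). Stage 1 proceeds at the
  potential rate until cumulative Es since the last rewetting reaches *U*
  (10 mm sandy loam, 12 mm clay loam); stage 2 then supplies
  `cona × (√t − √(t−1))` (cona 2 / 4 mm). Infiltration offsets the stage-1
  accumulator mm-for-mm; once it drops below *U* the surface is back in
  stage 1. Stage-2 time advances even on zero-demand days (stage-2 drying
  is time-driven, not demand-driven). Es is taken from the surface layer
  only, floored at an air-dry content of 0.6 × LL (deeper layers floor at
  LL). Potential soil evaporation is the Priestley–Taylor value reduced by
  canopy cover and mulch (below).
* **Root extraction.** Potential supply per rooted layer is
  `KL × (θ − LL) × Δz` (pro-rated in the layer containing the root
  front); uptake = min(demand, total supply), removed proportionally to
  per-layer supply.
* **Potential evaporation.** Priestley–Taylor over equilibrium
  evaporation with weighted mean temperature `0.75·Tmax + 0.25·Tmin`,
  albedo 0.13, and α = 1.40. The classic α = 1.26 applies to
  non-advective conditions; 1.40 reflects the regional advection of a
  semi-arid irrigated plain and brings seasonal crop water use closer to
  pan-based expectations. α is the single most influential constant for
  irrigation counts.

Every simulated season is audited:
`rain + irrigation − Es − T − runoff − drainage − ΔS = 0` to ≤ 0.1 mm
(observed ~1e-13, i.e. machine precision). All flux accounting runs from
the 15 October initialisation through maturity; pre-sowing soil
evaporation is genuine seasonal Es (and is where mulch saves most).
`dswc_mm` reports the conventional harvest-minus-sowing storage change;
`dswc_init_mm` is the closure-consistent harvest-minus-initialisation
term.

## Mulch

Cover = `1 − exp(−Am × mass)` with Am = 0.0004 ha kg⁻¹ (8 t ha⁻¹ → 0.959).
Potential soil evaporation after shading:
`eos = Eo × (1 − crop_cover) × (1 − residue_cover)^p`. The exponent
p = 0.6 is the mulch calibration constant: it sets the seasonal Es saving,
targeted at the observed 20–60 mm band (means ≈ 37 mm sandy loam, 44 mm
clay loam, the clay loam higher because of its larger stage-1 capacity
U = 12 vs 10 mm). Residue mass is constant within a season (wheat-season
decomposition is slow) and the mulch does not intercept rain or
irrigation. Mulch's soil-temperature effect on development is represented
only through the mulched cultivar preset (tt_floral_initiation = 450
vs 400 °Cd), not mechanistically.

## Crop

Phases: sowing → emergence (80 °Cd + 10 °Cd per cm sowing depth; 130 °Cd
at the standard 5 cm) → floral initiation (400/450 °Cd under the
vernalisation/photoperiod modifier) → anthesis (550 °Cd) → maturity
(750 °Cd).

* **Thermal time**: trapezoid (0, 26, 30, 40) °C with a 26 °Cd plateau,
  averaged over the classic eight diurnal temperature fractions
  `0.931 + 0.114 i − 0.0703 i² + 0.0053 i³`.
* **Vernalisation**: vernal days accrue as the fraction of the eight
  diurnal points within 0–15 °C;
  `vf = 1 − 0.0054545 × 1.7 × (50 − VD)`, saturating at VD = 50.
* **Photoperiod**: `pf = 1 − 0.002 × 3.8 × (20 − daylength)²`, daylength
  from standard solar geometry with civil twilight (−6°) at 30.9° N.
  The vegetative phase advances at `tt × min(vf, pf)`.
* **The 550 °Cd floral-initiation→anthesis phase** is a calibration
  constant (physiologically, stem elongation through heading). It places
  anthesis for a 10 November sowing in late February and maturity in
  early April, and keeps the mulch anthesis delay for late-October
  sowings at 8–9 days.
* **Canopy**: leaf area expands on a thermal-time-paced logistic,
  `dLAI = 0.012 × tt × LAI × (1 − LAI/6) × swdef`, from LAI 0.05 at
  emergence. A thermal pacing (rather than a biomass/SLA route) is used
  so that warm weather accelerates canopy and phenology together — under
  Ludhiana's dim winters (5.4–6.8 MJ m⁻² d⁻¹) a radiation-limited canopy
  cannot close in the observed time. During grain fill the canopy stays
  fully green for the first 40% of the phase, then declines linearly to
  zero at maturity.
* **Growth**: `ΔB = radn × (1 − exp(−0.5 LAI)) × 1.24 × f_T × swdef`,
  with f_T = 1 up to a mean temperature of 26 °C, declining linearly to 0
  at 40 °C.
* **Grain number** = 37.5 grains per g stem × (0.6 × biomass at
  anthesis). 37.5 is calibrated so the 40-year mean potential grain
  number for a 10 November sowing is ≈ 12,800 m⁻².
* **Grain filling**: 0.050 mg per grain per °Cd (≈ 37.5 mg per grain over
  a full 750 °Cd fill), capped at 41 mg per grain and at a harvest index
  of 0.55 of accumulated biomass. Tmax above 34 °C multiplies the rate by
  `1 − 0.04 × (Tmax − 34)` and accelerates senescence by adding
  `0.08 × (Tmax − 34) × tt` of extra phase time (shorter fill, smaller
  grains — terminal heat stress).
* **Water stress**: `swdef_photo = min(1, supply/demand)`, demand
  `= Eo × (1 − exp(−0.5 LAI))`. Nitrogen is non-limiting throughout (the
  120 kg ha⁻¹ initial mineral N is recorded metadata only). Roots descend
  at 15 mm d⁻¹ from sowing depth to 180 cm.

## Irrigation scheduling

Once daily, after the water-balance update and only between sowing and
maturity: if the 0–60 cm deficit has reached `threshold × PAWC(0–60)`,
apply `1.2 × deficit` the same day (at most one application per day).
`rainfed` never irrigates. `potential` (non-limiting water) forces the
stress factor to 1 and skips irrigation accounting; soil water is still
tracked and transpiration is still capped by root supply so the balance
closes.

## Scenarios and initial conditions

Each season re-initialises on 15 October (post-rice): soil water at 80%
of DUL in the top 30 cm and at DUL below (initial available water 316 mm
clay loam, 273 mm sandy loam over 0–180 cm), mulch applied the same day,
no carry-over between years. Sowing dates before 15 October's nominal
initialisation (Scenario 1's 10 October) initialise on the sowing day.
Scenario 1: nine sowing dates 10 Oct–30 Dec × {potential, 50% SWD} × two
soils. Scenario 2: seven sowings 15 Oct–30 Nov × {mulch, bare} at 50%
SWD. Scenario 3: thresholds 10–70% SWD plus rainfed × {mulch, bare},
sown 7 November. Defaults run 40 independent synthetic years.

## Synthetic weather

The generator emulates the Ludhiana station's monthly statistics, not its
history:

* Monthly normals for November–April are station values; October and May
  are gradient extrapolations from adjacent months, and June–September
  (monsoon, never touched by a wheat season that ends in June) are
  climatological placeholders. The `observed` flag in
  `data/ludhiana_normals.yaml` marks the assumed months.
* Temperature and radiation follow piecewise-linear seasonal curves
  between month midpoints whose knots are iteratively corrected so every
  month's long-run mean equals its normal; daily anomalies are AR(1)
  (ρ = 0.6) with a shared synoptic component, sd ≈ 2.5 °C.
* Monthly rain totals are gamma (shape 0.75, strongly skewed) with the
  underlying mean adjusted so the range-truncated mean equals the normal;
  the total is split across `1 + Poisson(min(4, total/15))` event days by
  a Dirichlet(0.8) allocation. ≈ 93% of wheat-season days are dry.
* Wet-day radiation is multiplied by 0.6 (cloud), with the clear-sky base
  raised by the expected wet-day fraction so monthly means still recover.

At 200 years the climatology recovers the normals within 0.15 °C,
0.5 MJ m⁻² d⁻¹ and ~10% on monthly rainfall, and all monthly totals fall
inside the printed ranges.

What it does **not** emulate: the real record's regime-scale anomalies —
multi-month fog/low-radiation winters (the kind that produced the record
minimum-yield season) or single 100 mm deluges beyond the printed monthly
ranges. Year-to-year variance in simulated yields is therefore narrower
than the 40-year station record's, and tests built on synthetic weather
check patterns and bands, not historical magnitudes.

## Numerical choices and degenerate inputs

Dates are strictly daily with no gaps (validated with row numbers on
file input). The season loop terminates at physiological maturity, with a
hard failsafe at 30 June. Ties at the irrigation threshold trigger (≥).
`WP_I` is undefined (NaN) for rainfed seasons; summary tables report both
the mean of per-year WP ratios and the ratio of group means, since both
conventions appear in field practice. The "maximum tillering" date used
for photothermal-quotient windows is when the vegetative phase reaches
60% of its thermal-time target. Mean irrigation *numbers* decrease
strictly with the scheduling threshold; mean *amounts* are compared after
averaging over the mulch factor because at ~2 events per season the
120%-of-deficit application makes single-treatment amounts discrete and
noisy.

## Known limitations

* Transpiration demand is `Eo × cover` rather than a vapour-pressure-
  deficit/transpiration-efficiency form; in this climate that caps
  seasonal water stress well below what a VPD-driven model produces, so
  rainfed yields decline only mildly rather than collapsing. The water-
  balance side (depletion, dSWC signs, irrigation counts by threshold) is
  unaffected.
* The sowing-date yield response is flat-to-slightly-increasing rather
  than humped around mid-November, and mulch is never yield-negative for
  very late sowings: with grain filling ending in early April, synthetic
  heat exposure (a few >34 °C days) is too small to overturn the longer
  duration of late sowings. The directional heat patterns (more hot days
  with later sowing and with mulch) are reproduced.
* No capillary rise, solute transport, residue decomposition, rainfall
  interception by residue, N cycling, tillering dynamics, pests or CO₂
  response.
* Grain number and per-grain mass are calibrated jointly to the published
  grain-number mean and the potential-yield envelope; the published
  minimum-year combination (5,700 grains at 3.0 t ha⁻¹) is arithmetically
  inconsistent with yield = number × mass at any realistic grain mass and
  cannot be matched simultaneously.
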