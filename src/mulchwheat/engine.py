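"""Season simulation and multi-year scenario experiments.

A season starts on 15 October (typical rice harvest; wet profile, mulch
applied if any) and runs a daily loop — potential evaporation, canopy and
residue partitioning, irrigation decision, infiltration/drainage/runoff,
two-stage soil evaporation, thermal time and phenology, root water uptake
and stress, biomass growth and grain filling — until physiological
maturity.  Seasons are independent: the profile is re-initialised every
15 October and there is no carry-over.

Three scenario designs are provided: (1) sowing date x {potential water,
irrigation at 50% soil water deficit} on both soils, (2) sowing date x
mulch at 50% SWD scheduling, (3) irrigation threshold (10-70% SWD, plus
rainfed) x mulch for a 7 November sowing.  Every season's water balance is
audited for closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date as Date

import numpy as np
import pandas as pd

from . import crop as cr
from . import soil as sw
from .crop import CropParams, CropState, Stage
from .irrigation import IrrigationPolicy, irrigation_amount, should_irrigate
from .presets import load_cultivar, load_soil, ludhiana_normals
from .residue import ResidueState, adjust_potential_soil_evaporation
from .weather import WeatherSeries, generate_synthetic_weather

__all__ = [
    "ScenarioConfig",
    "SeasonResult",
    "run_season",
    "run_scenario",
    "water_balance_audit",
    "SCENARIO_SOWING_DATES",
    "SCENARIO3_THRESHOLDS",
]

SCENARIO_SOWING_DATES = {
    1: ((10, 10), (10, 20), (10, 30), (11, 10), (11, 20), (11, 30),
        (12, 10), (12, 20), (12, 30)),
    2: ((10, 15), (10, 23), (10, 31), (11, 7), (11, 15), (11, 23), (11, 30)),
    3: ((11, 7),),
}
SCENARIO3_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

HOT_GRAINFILL_THRESHOLD = 34.0  # degC


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario experiment: factors, years and initial conditions."""

    scenario: int
    soils: tuple = ("sandy_loam", "clay_loam")
    mulches: tuple = (False,)
    sowing_dates: tuple = SCENARIO_SOWING_DATES[1]
    policies: tuple = (IrrigationPolicy("potential"), IrrigationPolicy(threshold=0.5))
    years: int = 40
    seed: int = 1
    init_month_day: tuple = (10, 15)
    init_top_fraction: float = 0.8
    init_top_depth_mm: float = 300.0
    mulch_mass_kg_ha: float = 8000.0
    sowing_depth_mm: float = 50.0
    plant_density_m2: float = 150.0   # metadata: density and row spacing are
    row_spacing_mm: float = 200.0     # not free parameters of this model
    initial_mineral_n_kg_ha: float = 120.0  # recorded only; N is non-limiting

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        for m, d in self.sowing_dates:
            if not (Date(2000, 10, 1) <= Date(2000, m, d) <= Date(2000, 12, 31)):
                raise ValueError("sowing dates must lie in 1 Oct - 31 Dec")

    @classmethod
    def for_scenario(cls, scenario: int, years: int = 40, seed: int = 1,
                     **overrides) -> "ScenarioConfig":
        """The three designs with their published factor sets."""
        if scenario == 1:
            kw = dict(mulches=(False,), sowing_dates=SCENARIO_SOWING_DATES[1],
                      policies=(IrrigationPolicy("potential"),
                                IrrigationPolicy(threshold=0.5)))
        elif scenario == 2:
            kw = dict(mulches=(False, True), sowing_dates=SCENARIO_SOWING_DATES[2],
                      policies=(IrrigationPolicy(threshold=0.5),))
        elif scenario == 3:
            kw = dict(mulches=(False, True), sowing_dates=SCENARIO_SOWING_DATES[3],
                      policies=tuple(IrrigationPolicy(threshold=t)
                                     for t in SCENARIO3_THRESHOLDS)
                      + (IrrigationPolicy("rainfed"),))
        else:
            raise ValueError("scenario must be 1, 2 or 3")
        kw.update(overrides)
        return cls(scenario=scenario, years=years, seed=seed, **kw)


@dataclass
class SeasonResult:
    """Outputs of one treatment-year."""

    year: int
    soil: str
    mulch: bool
    sowing_date: Date
    policy: str
    anthesis_date: Date | None
    maturity_date: Date | None
    max_tillering_date: Date | None
    yield_kg_ha: float
    grain_number_m2: float
    mean_grain_wt_mg: float
    biomass_g_m2: float
    biomass_anthesis_g_m2: float
    irrigation_n: int
    irrigation_mm: float
    rain_mm: float
    es_mm: float
    transpiration_mm: float
    et_mm: float
    drainage_mm: float
    runoff_mm: float
    dswc_mm: float            # stored water, harvest minus sowing (0-180 cm)
    dswc_init_mm: float       # stored water, harvest minus 15 Oct initialisation
    mean_stress_index: float
    hot_grainfill_days: int
    wp_et: float
    wp_i: float
    closure_mm: float


def run_season(
    profile: sw.SoilProfile,
    params: CropParams,
    policy: IrrigationPolicy,
    weather: WeatherSeries,
    sowing_date: Date,
    mulch_mass_kg_ha: float = 0.0,
    init_date: Date | None = None,
    init_top_fraction: float = 0.8,
    init_top_depth_mm: float = 300.0,
    sowing_depth_mm: float = 50.0,
    year_label: int | None = None,
    soil_name: str | None = None,
) -> SeasonResult:
    """Simulate one season from initialisation to physiological maturity.

    ``weather`` must cover ``init_date`` (default 15 October of the sowing
    year) through the following 30 June.  The water balance runs from
    initialisation (pre-sowing soil evaporation depletes the seedbed and is
    part of seasonal Es); all flux components and the closure audit cover
    the initialisation-to-maturity window, while ``dswc_mm`` additionally
    reports the conventional harvest-minus-sowing storage change.
    """
    if init_date is None:
        init_date = Date(sowing_date.year, 10, 15)
    if sowing_date < init_date:
        raise ValueError("sowing date precedes initialisation date")
    end_date = Date(sowing_date.year + 1, 6, 30)

    sl = weather.slice(init_date, end_date)
    f = sl.frame
    if len(f) == 0 or f["date"].iloc[0].date() != init_date:
        raise ValueError("weather does not cover the season window")
    if f["date"].iloc[-1].date() < Date(sowing_date.year + 1, 5, 31):
        raise ValueError("weather window must extend through at least 31 May")
    dates = f["date"].dt.date.to_numpy()
    doy = f["date"].dt.dayofyear.to_numpy()
    tmax_a = f["tmax"].to_numpy()
    tmin_a = f["tmin"].to_numpy()
    radn_a = f["radn"].to_numpy()
    rain_a = f["rain"].to_numpy()
    lat = weather.latitude

    state = sw.initialize_profile_water(profile, init_top_fraction, init_top_depth_mm)
    residue = ResidueState(mulch_mass_kg_ha)
    plant = CropState(sowing_depth_mm=sowing_depth_mm)
    pawc60 = sw.compute_pawc(profile, policy.monitored_depth_mm)
    potential_mode = policy.mode == "potential"

    init_storage = state.storage_mm(profile)
    sow_storage = init_storage
    rain_sum = irr_sum = t_sum = 0.0
    irr_n = 0
    hot_days = 0
    anthesis_date = maturity_date = max_till_date = None

    for i in range(len(dates)):
        today = dates[i]
        tmax, tmin, radn, rain = tmax_a[i], tmin_a[i], radn_a[i], rain_a[i]

        if plant.stage == Stage.PRESOW and today >= sowing_date:
            plant.stage = Stage.SOWN
            plant.root_depth_mm = sowing_depth_mm
            sow_storage = state.storage_mm(profile)

        eo = sw.potential_evapotranspiration(tmax, tmin, radn)
        green_lai = cr.senesced_lai(plant, params)
        crop_cover = 1.0 - np.exp(-params.extinction_k * green_lai)
        eos = adjust_potential_soil_evaporation(eo, residue.cover, crop_cover,
                                                residue.exponent)

        in_season = Stage.SOWN <= plant.stage < Stage.MATURE
        irr = 0.0
        if policy.mode == "swd_threshold" and in_season:
            swd = sw.soil_water_deficit(state, profile, policy.monitored_depth_mm)
            if should_irrigate(swd, pawc60, policy):
                irr = irrigation_amount(swd, policy)
                irr_n += 1
        sw.infiltrate_and_drain(state, profile, rain + irr)
        sw.soil_evaporation_step(state, profile, eos)
        rain_sum += rain
        irr_sum += irr

        if not in_season:
            continue

        tt = cr.daily_thermal_time(tmax, tmin, params.trap_x, params.trap_y)
        if plant.stage == Stage.EMERGED:
            plant.cum_vern_days += cr.vernal_day_increment(tmax, tmin)
            vf = cr.vernalization_factor(plant.cum_vern_days, params.vern_sens)
            pf = cr.photoperiod_factor(cr.day_length(int(doy[i]), lat),
                                       params.photop_sens)
        else:
            vf = pf = 1.0

        plant.root_depth_mm = min(
            min(params.max_root_depth_mm, profile.depth_mm),
            plant.root_depth_mm + params.root_front_velocity_mm_day)

        crossed = cr.advance_phenology(plant, params, tt, vf, pf)
        if crossed:
            if plant.stage == Stage.EMERGED:
                plant.lai = params.lai_at_emergence
            elif plant.stage == Stage.ANTHESIS:
                cr.set_grain_number(plant, params)
                anthesis_date = today
            elif plant.stage == Stage.MATURE:
                maturity_date = today
                break
        if (plant.stage == Stage.EMERGED and max_till_date is None
                and plant.tt_phase >= 0.6 * params.tt_floral_initiation):
            max_till_date = today

        if plant.stage >= Stage.EMERGED:
            demand = cr.transpiration_demand(green_lai, params.extinction_k, eo)
            supply = float(sw.water_supply(state, profile, plant.root_depth_mm).sum())
            stress = 1.0 if potential_mode else cr.swdef_photo(supply, demand)
            uptake = sw.extract_transpiration(state, profile, demand,
                                              plant.root_depth_mm)
            t_sum += uptake
            plant.stress_sum += stress
            plant.stress_days += 1
            cr.daily_growth(plant, params, radn, stress, (tmax + tmin) / 2.0, tt)
            if plant.stage == Stage.ANTHESIS:
                cr.grain_fill_step(plant, params, tt, tmax)
                if tmax > HOT_GRAINFILL_THRESHOLD:
                    hot_days += 1

    if maturity_date is None:  # failsafe: season truncated at the window end
        maturity_date = dates[-1]

    es_sum = state.es_mm
    drain_sum = state.drain_mm
    runoff_sum = state.runoff_mm
    end_storage = state.storage_mm(profile)
    dswc = end_storage - sow_storage
    dswc_init = end_storage - init_storage
    et = es_sum + t_sum
    closure = rain_sum + irr_sum - et - drain_sum - runoff_sum - dswc_init

    yield_kg = plant.grain_mass * 10.0  # g m-2 -> kg ha-1
    grain_wt = (plant.grain_mass / plant.grain_number * 1000.0
                if plant.grain_number > 0 else 0.0)
    return SeasonResult(
        year=year_label if year_label is not None else sowing_date.year,
        soil=soil_name or profile.name,
        mulch=mulch_mass_kg_ha > 0,
        sowing_date=sowing_date,
        policy=policy.label,
        anthesis_date=anthesis_date,
        maturity_date=maturity_date,
        max_tillering_date=max_till_date,
        yield_kg_ha=yield_kg,
        grain_number_m2=plant.grain_number,
        mean_grain_wt_mg=grain_wt,
        biomass_g_m2=plant.biomass,
        biomass_anthesis_g_m2=plant.stem_biomass_anthesis
        / params.stem_frac_at_anthesis if plant.stem_biomass_anthesis else 0.0,
        irrigation_n=irr_n,
        irrigation_mm=irr_sum,
        rain_mm=rain_sum,
        es_mm=es_sum,
        transpiration_mm=t_sum,
        et_mm=et,
        drainage_mm=drain_sum,
        runoff_mm=runoff_sum,
        dswc_mm=dswc,
        dswc_init_mm=dswc_init,
        mean_stress_index=(plant.stress_sum / plant.stress_days
                           if plant.stress_days else 1.0),
        hot_grainfill_days=hot_days,
        wp_et=yield_kg / et if et > 0 else 0.0,
        wp_i=yield_kg / irr_sum if irr_sum > 0 else float("nan"),
        closure_mm=closure,
    )


def run_scenario(config: ScenarioConfig,
                 weather: WeatherSeries | None = None) -> pd.DataFrame:
    """Full factorial of the configured factors x years; one row per season.

    If no weather is supplied, a synthetic multi-year Ludhiana-like series
    is generated from ``config.seed`` (one extra calendar year so every
    season reaches the following June).
    """
    if weather is None:
        weather = generate_synthetic_weather(ludhiana_normals(),
                                             config.years + 1, config.seed)
    start_year = int(weather.frame["date"].iloc[0].year)
    profiles = {s: load_soil(s) for s in config.soils}
    rows = []
    for year_idx in range(config.years):
        yr = start_year + year_idx
        init = Date(yr, *config.init_month_day)
        season_weather = weather.slice(Date(yr, 10, 1), Date(yr + 1, 6, 30))
        for soil_name, profile in profiles.items():
            for mulch in config.mulches:
                params = load_cultivar("pbw343_mulch" if mulch else "pbw343_bare")
                mass = config.mulch_mass_kg_ha if mulch else 0.0
                for m, d in config.sowing_dates:
                    # sowings earlier than the nominal 15 Oct initialisation
                    # (Scenario 1's 10 Oct) initialise on the sowing day
                    sow = Date(yr, m, d)
                    for policy in config.policies:
                        res = run_season(
                            profile, params, policy, season_weather,
                            sow, mulch_mass_kg_ha=mass,
                            init_date=min(init, sow),
                            init_top_fraction=config.init_top_fraction,
                            init_top_depth_mm=config.init_top_depth_mm,
                            sowing_depth_mm=config.sowing_depth_mm,
                            year_label=year_idx, soil_name=soil_name,
                        )
                        rows.append(asdict(res))
    out = pd.DataFrame(rows)
    # calendar sowing date (year-independent) for grouping across years
    out.insert(4, "sowing", [d.strftime("%d-%b") for d in out["sowing_date"]])
    return out


def water_balance_audit(result: SeasonResult | pd.Series) -> float:
    """Closure error (mm): rain + irrigation - ET - drainage - runoff - dSWC,
    with every term over the initialisation-to-maturity window."""
    r = result if isinstance(result, pd.Series) else pd.Series(asdict(result))
    return float(r["rain_mm"] + r["irrigation_mm"] - r["et_mm"]
                 - r["drainage_mm"] - r["runoff_mm"] - r["dswc_init_mm"])
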