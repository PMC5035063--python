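"""CERES/APSIM-style wheat growth and development.

Phenology runs on thermal time from a trapezoidal temperature response
evaluated at eight diurnal temperature fractions.  Progress from emergence
to floral initiation is slowed by the more limiting of a vernalisation
factor (cool-day accumulation, sensitivity ``vern_sens``) and a photoperiod
factor (day length, sensitivity ``photop_sens``).  Biomass accumulates as
intercepted radiation x radiation-use efficiency, down-weighted by a
high-temperature factor (declining above 26 degC) and the soil water stress
index swdef_photo.  Grain number is set from stem biomass at anthesis;
grain filling proceeds per degree-day with rate and duration penalties when
Tmax exceeds 34 degC (terminal heat stress).  Nutrients are non-limiting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
import math

import numpy as np

__all__ = [
    "Stage",
    "CropParams",
    "CropState",
    "daily_thermal_time",
    "diurnal_temperatures",
    "vernal_day_increment",
    "vernalization_factor",
    "photoperiod_factor",
    "day_length",
    "advance_phenology",
    "daily_growth",
    "set_grain_number",
    "grain_fill_step",
    "swdef_photo",
    "transpiration_demand",
]

# Classic 8-point diurnal interpolation weights: fraction of the Tmin-Tmax
# range at each 3-hourly node.
_TMFAC = np.array(
    [0.931 + 0.114 * i - 0.0703 * i**2 + 0.0053 * i**3 for i in range(1, 9)]
)


class Stage(IntEnum):
    PRESOW = 0
    SOWN = 1
    EMERGED = 2          # vegetative: accumulating toward floral initiation
    FLORAL_INIT = 3      # bridge to anthesis
    ANTHESIS = 4         # grain filling
    MATURE = 5


@dataclass(frozen=True)
class CropParams:
    """Cultivar coefficients; two presets differ only in tt_floral_initiation."""

    startgf_to_mat: float = 750.0
    tt_floral_initiation: float = 400.0
    vern_sens: float = 1.7
    photop_sens: float = 3.8
    trap_x: tuple = (0.0, 26.0, 30.0, 40.0)
    trap_y: tuple = (0.0, 26.0, 26.0, 0.0)
    rue: float = 1.24
    extinction_k: float = 0.50
    grains_per_g_stem: float = 37.5
    max_grain_wt_mg: float = 41.0
    grain_fill_rate_mg_degday: float = 0.050
    stem_frac_at_anthesis: float = 0.60
    tt_emergence_base: float = 80.0
    tt_per_cm_sowing_depth: float = 10.0
    tt_floral_to_anthesis: float = 550.0
    lai_expansion_per_degday: float = 0.012
    lai_max: float = 6.0
    lai_at_emergence: float = 0.05
    root_front_velocity_mm_day: float = 15.0
    max_root_depth_mm: float = 1800.0
    rue_temp_threshold: float = 26.0
    rue_temp_cut: float = 40.0
    fill_heat_threshold: float = 34.0
    fill_heat_slope: float = 0.04
    senescence_accel: float = 0.08
    stay_green_frac: float = 0.4   # fraction of grain fill before senescence
    max_harvest_index: float = 0.55

    def tt_emergence(self, sowing_depth_mm: float) -> float:
        return (self.tt_emergence_base
                + self.tt_per_cm_sowing_depth * sowing_depth_mm / 10.0)


@dataclass
class CropState:
    """Daily phenology, biomass and grain state of one crop."""

    stage: Stage = Stage.PRESOW
    tt_phase: float = 0.0          # thermal time within the current phase
    cum_vern_days: float = 0.0
    biomass: float = 0.0           # g m-2, above-ground
    stem_biomass_anthesis: float = 0.0
    lai: float = 0.0
    lai_anthesis: float = 0.0
    root_depth_mm: float = 0.0
    grain_number: float = 0.0      # grains m-2
    grain_mass: float = 0.0        # g m-2
    sowing_depth_mm: float = 50.0
    stress_sum: float = 0.0        # for the mean water stress index
    stress_days: int = 0


def diurnal_temperatures(tmax: float, tmin: float) -> np.ndarray:
    """Eight 3-hourly temperatures interpolated between Tmin and Tmax."""
    return tmin + _TMFAC * (tmax - tmin)


def daily_thermal_time(tmax: float, tmin: float,
                       trap_x=(0.0, 26.0, 30.0, 40.0),
                       trap_y=(0.0, 26.0, 26.0, 0.0)) -> float:
    """Daily thermal time: trapezoidal response averaged over 8 diurnal
    temperature fractions, degC d.  Zero below the base and above the upper
    lethal temperature; a plateau between the two optima."""
    if tmax < tmin:
        raise ValueError("tmax must be >= tmin")
    temps = diurnal_temperatures(tmax, tmin)
    resp = np.interp(temps, trap_x, trap_y, left=0.0, right=0.0)
    return float(resp.mean())


def vernal_day_increment(tmax: float, tmin: float,
                         lo: float = 0.0, hi: float = 15.0) -> float:
    """Fraction of a vernal day accrued: share of the 8 diurnal temperature
    points lying in the cool window [lo, hi] degC."""
    temps = diurnal_temperatures(tmax, tmin)
    return float(np.mean((temps >= lo) & (temps <= hi)))


def vernalization_factor(cum_vern_days: float, vern_sens: float) -> float:
    """1 - 0.0054545 x vern_sens x (50 - cumVD), clamped to [0, 1]."""
    if cum_vern_days >= 50.0:
        return 1.0
    f = 1.0 - 0.0054545 * vern_sens * (50.0 - cum_vern_days)
    return min(1.0, max(0.0, f))


def photoperiod_factor(day_length_h: float, photop_sens: float) -> float:
    """1 - 0.002 x photop_sens x (20 - day length)^2, clamped to [0, 1]."""
    f = 1.0 - 0.002 * photop_sens * (20.0 - day_length_h) ** 2
    return min(1.0, max(0.0, f))


def day_length(doy: int, latitude_deg: float, twilight_deg: float = -6.0) -> float:
    """Astronomical day length (h) including a twilight sun-angle offset.

    Standard solar geometry: the sun is "up" while its altitude exceeds
    ``twilight_deg`` (the CERES photoperiod convention uses civil twilight,
    -6 degrees).
    """
    if abs(latitude_deg) >= 66.0:
        raise ValueError("polar latitudes not supported")
    lat = math.radians(latitude_deg)
    decl = math.radians(23.45 * math.sin(2.0 * math.pi * (284 + doy) / 365.0))
    a = math.radians(twilight_deg)
    cos_ws = (math.sin(a) - math.sin(lat) * math.sin(decl)) / (
        math.cos(lat) * math.cos(decl))
    cos_ws = min(1.0, max(-1.0, cos_ws))
    return 24.0 / math.pi * math.acos(cos_ws)


def phase_target(state: CropState, params: CropParams) -> float:
    """Thermal-time target of the current phase, degC d."""
    if state.stage == Stage.SOWN:
        return params.tt_emergence(state.sowing_depth_mm)
    if state.stage == Stage.EMERGED:
        return params.tt_floral_initiation
    if state.stage == Stage.FLORAL_INIT:
        return params.tt_floral_to_anthesis
    if state.stage == Stage.ANTHESIS:
        return params.startgf_to_mat
    return math.inf


def advance_phenology(state: CropState, params: CropParams, tt_today: float,
                      vf: float = 1.0, pf: float = 1.0) -> bool:
    """Accumulate thermal time and advance the stage machine.

    The vegetative (emergence to floral initiation) phase progresses at
    tt x min(vf, pf); all other phases use unmodified thermal time.
    Returns True when a stage boundary was crossed today.
    """
    if state.stage in (Stage.PRESOW, Stage.MATURE):
        return False
    tt_eff = tt_today * min(vf, pf) if state.stage == Stage.EMERGED else tt_today
    state.tt_phase += tt_eff
    if state.tt_phase >= phase_target(state, params):
        state.tt_phase = 0.0
        state.stage = Stage(state.stage + 1)
        return True
    return False


def rue_temperature_factor(tmean: float, params: CropParams) -> float:
    """1 up to 26 degC, declining linearly to 0 at the upper cut."""
    if tmean <= params.rue_temp_threshold:
        return 1.0
    span = params.rue_temp_cut - params.rue_temp_threshold
    return max(0.0, 1.0 - (tmean - params.rue_temp_threshold) / span)


def daily_growth(state: CropState, params: CropParams, radn: float,
                 swdef: float, tmean: float, tt_today: float = 0.0) -> float:
    """Biomass increment (g m-2): intercepted radiation x RUE x stresses.

    Leaf area expands on a thermal-time-paced logistic during the
    vegetative and bridge phases (warm weather accelerates canopy and
    phenology together), scaled by the water stress index.  Mutates
    ``state``.
    """
    if state.stage < Stage.EMERGED or state.stage == Stage.MATURE:
        return 0.0
    cover = 1.0 - math.exp(-params.extinction_k * senesced_lai(state, params))
    db = radn * cover * params.rue * rue_temperature_factor(tmean, params) * swdef
    state.biomass += db
    if state.stage < Stage.ANTHESIS:
        state.lai += (params.lai_expansion_per_degday * tt_today * state.lai
                      * max(0.0, 1.0 - state.lai / params.lai_max) * swdef)
    return db


def set_grain_number(state: CropState, params: CropParams) -> None:
    """At anthesis: grains m-2 = grains_per_g_stem x stem biomass, where the
    stem is a fixed fraction of total biomass at anthesis."""
    if state.stage != Stage.ANTHESIS:
        raise ValueError("grain number is set at anthesis")
    state.stem_biomass_anthesis = params.stem_frac_at_anthesis * state.biomass
    state.grain_number = params.grains_per_g_stem * state.stem_biomass_anthesis
    state.lai_anthesis = state.lai


def grain_fill_step(state: CropState, params: CropParams, tt_today: float,
                    tmax: float) -> float:
    """One grain-filling day; returns the grain mass increment (g m-2).

    Tmax above the heat threshold both slows the filling rate (f_fill) and
    accelerates senescence — the remaining phase is shortened by counting
    extra effective thermal time.  Per-grain mass is capped at
    max_grain_wt_mg, and total grain cannot exceed the harvest-index cap of
    accumulated biomass (grain growth is assimilate-limited).
    """
    if state.stage != Stage.ANTHESIS or state.grain_number <= 0:
        return 0.0
    over = max(0.0, tmax - params.fill_heat_threshold)
    f_fill = max(0.0, 1.0 - params.fill_heat_slope * over)
    dm_mg = state.grain_number * params.grain_fill_rate_mg_degday * tt_today * f_fill
    dm = dm_mg / 1000.0  # mg m-2 -> g m-2
    cap_number = state.grain_number * params.max_grain_wt_mg / 1000.0
    cap_hi = params.max_harvest_index * state.biomass
    dm = max(0.0, min(dm, cap_number - state.grain_mass, cap_hi - state.grain_mass))
    state.grain_mass += dm
    # accelerated senescence: extra effective thermal time within the phase
    state.tt_phase += params.senescence_accel * over * tt_today
    return dm


def senesced_lai(state: CropState, params: CropParams) -> float:
    """Green LAI during grain fill: full canopy through the stay-green
    portion of the phase, then a linear decline to zero at maturity."""
    if state.stage < Stage.ANTHESIS:
        return state.lai
    if state.stage == Stage.MATURE:
        return 0.0
    frac = min(1.0, state.tt_phase / params.startgf_to_mat)
    if frac <= params.stay_green_frac:
        return state.lai_anthesis
    frac_left = (1.0 - frac) / (1.0 - params.stay_green_frac)
    return state.lai_anthesis * frac_left


def swdef_photo(supply: float, demand: float) -> float:
    """Water stress index for photosynthesis: min(1, supply/demand);
    1 (no stress) when demand is zero."""
    if supply < 0 or demand < 0:
        raise ValueError("supply and demand must be non-negative")
    if demand == 0.0:
        return 1.0
    return min(1.0, supply / demand)


def transpiration_demand(lai: float, extinction_k: float, eo: float) -> float:
    """Crop water demand: Eo x green cover, with cover = 1 - exp(-k LAI)."""
    return eo * (1.0 - math.exp(-extinction_k * lai))
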