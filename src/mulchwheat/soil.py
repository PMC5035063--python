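"""Layered cascading soil water balance.

The profile is a stack of layers (surface first, depths in mm) each holding
water volumetrically between a crop lower limit (LL), a drained upper limit
(DUL, field capacity) and saturation (SAT).  Infiltrating water fills layers
top-down to SAT; surface excess ponds behind the field bund and only the
spill above bund height runs off.  Each day every layer passes
SWCON x (content above DUL) to the layer below; flux leaving the bottom
layer is deep drainage.  Soil evaporation follows the Ritchie two-stage
model (stage 1 energy-limited up to U mm since last rewetting, stage 2
supply-limited at cona x (sqrt(t) - sqrt(t-1)) mm per day), and root water
uptake is limited per layer by KL x available water.

All fluxes are in mm of water; layer contents are volumetric fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "SoilWaterState",
    "compute_pawc",
    "initialize_profile_water",
    "available_water",
    "soil_water_deficit",
    "infiltrate_and_drain",
    "potential_evapotranspiration",
    "soil_evaporation_step",
    "water_supply",
    "extract_transpiration",
]

#: The surface layer may evaporate down to this multiple of its LL.
AIRDRY_LL_FRACTION = 0.6

#: Priestley-Taylor multiplier applied to equilibrium evaporation.
PT_COEFF = 1.40


@dataclass(frozen=True)
class SoilLayer:
    """Static hydraulic parameters of one soil layer."""

    thickness_mm: float
    ll: float
    dul: float
    sat: float
    bd: float
    swcon: float
    kl: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ll < self.dul < self.sat < 1.0):
            raise ValueError("require 0 < LL < DUL < SAT < 1")
        if not (0.0 <= self.swcon <= 1.0 and 0.0 <= self.kl <= 1.0):
            raise ValueError("SWCON and KL must lie in [0, 1]")
        if self.thickness_mm <= 0:
            raise ValueError("layer thickness must be positive")


@dataclass
class SoilProfile:
    """Ordered soil layers plus evaporation and bund parameters."""

    layers: list[SoilLayer]
    u_mm: float
    cona: float
    bund_mm: float = 100.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.u_mm <= 0 or self.cona <= 0:
            raise ValueError("U and cona must be positive")
        self.thickness = np.array([l.thickness_mm for l in self.layers])
        self.ll = np.array([l.ll for l in self.layers])
        self.dul = np.array([l.dul for l in self.layers])
        self.sat = np.array([l.sat for l in self.layers])
        self.swcon = np.array([l.swcon for l in self.layers])
        self.kl = np.array([l.kl for l in self.layers])
        self.bottoms = np.cumsum(self.thickness)
        self.airdry = self.ll.copy()
        self.airdry[0] *= AIRDRY_LL_FRACTION

    @property
    def depth_mm(self) -> float:
        return float(self.bottoms[-1])

    def layer_fractions(self, depth_mm: float) -> np.ndarray:
        """Fraction of each layer lying above ``depth_mm`` (pro-rated)."""
        if depth_mm < 0:
            raise ValueError("depth must be non-negative")
        tops = self.bottoms - self.thickness
        overlap = np.clip(depth_mm - tops, 0.0, self.thickness)
        return overlap / self.thickness


@dataclass
class SoilWaterState:
    """Dynamic per-layer water contents and evaporation bookkeeping."""

    theta: np.ndarray
    sumes1: float = 0.0       # stage-1 Es accumulated since last rewetting, mm
    t2: int = 0               # days since stage-2 onset
    pond_mm: float = 0.0      # surface storage behind the bund
    es_mm: float = 0.0        # season accumulators
    drain_mm: float = 0.0
    runoff_mm: float = 0.0

    def copy(self) -> "SoilWaterState":
        return SoilWaterState(self.theta.copy(), self.sumes1, self.t2,
                              self.pond_mm, self.es_mm, self.drain_mm,
                              self.runoff_mm)

    def storage_mm(self, profile: SoilProfile) -> float:
        """Total stored water (profile plus pond), mm."""
        return float(np.sum(self.theta * profile.thickness) + self.pond_mm)


def compute_pawc(profile: SoilProfile, depth_mm: float | None = None) -> float:
    """Plant available water capacity: sum of (DUL - LL) x thickness, mm.

    ``depth_mm`` may fall inside a layer, in which case the layer
    contributes pro-rata.  Defaults to the whole profile.
    """
    if depth_mm is None:
        depth_mm = profile.depth_mm
    frac = profile.layer_fractions(depth_mm)
    return float(np.sum((profile.dul - profile.ll) * profile.thickness * frac))


def initialize_profile_water(
    profile: SoilProfile, top_fraction: float = 0.8, top_depth_mm: float = 300.0
) -> SoilWaterState:
    """Initial water: ``top_fraction`` x DUL in layers fully above
    ``top_depth_mm``, DUL below — the wet profile left by ponded rice."""
    if not 0.0 <= top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in [0, 1]")
    if top_depth_mm > profile.depth_mm:
        raise ValueError("top_depth exceeds profile depth")
    theta = profile.dul.copy()
    in_top = profile.bottoms <= top_depth_mm + 1e-9
    theta[in_top] = top_fraction * profile.dul[in_top]
    theta = np.maximum(theta, profile.airdry)
    return SoilWaterState(theta=theta)


def available_water(state: SoilWaterState, profile: SoilProfile,
                    depth_mm: float | None = None) -> float:
    """Water held above LL over the stated depth, mm."""
    if depth_mm is None:
        depth_mm = profile.depth_mm
    frac = profile.layer_fractions(depth_mm)
    return float(np.sum(np.clip(state.theta - profile.ll, 0.0, None)
                        * profile.thickness * frac))


def soil_water_deficit(state: SoilWaterState, profile: SoilProfile,
                       depth_mm: float = 600.0) -> float:
    """mm of water needed to refill the stated depth to DUL."""
    frac = profile.layer_fractions(depth_mm)
    return float(np.sum(np.clip(profile.dul - state.theta, 0.0, None)
                        * profile.thickness * frac))


def infiltrate_and_drain(
    state: SoilWaterState, profile: SoilProfile, water_in: float
) -> tuple[float, float]:
    """Apply a day's rain + irrigation; cascade drainage; return fluxes.

    Mutates ``state`` in place and returns ``(runoff_mm, deep_drainage_mm)``.
    Ponded water from previous days infiltrates before any new runoff is
    generated; only surface excess beyond bund height leaves the field.
    Infiltration offsets the stage-1 evaporation accumulator mm-for-mm
    (rewetting), returning evaporation to stage 1 once fully offset.
    """
    if water_in < 0:
        raise ValueError("water_in must be non-negative")
    th, sat, dul, swcon = profile.thickness, profile.sat, profile.dul, profile.swcon

    supply = water_in + state.pond_mm
    remaining = supply
    for i in range(len(th)):
        cap = (sat[i] - state.theta[i]) * th[i]
        add = min(remaining, max(cap, 0.0))
        state.theta[i] += add / th[i]
        remaining -= add
        if remaining <= 0:
            break
    pond = min(remaining, profile.bund_mm)
    runoff = remaining - pond
    state.pond_mm = pond
    infiltrated = supply - pond - runoff

    # Cascade: each layer sheds SWCON of its water above DUL to the next.
    flux = 0.0
    for i in range(len(th)):
        state.theta[i] += flux / th[i]
        surplus = max(0.0, state.theta[i] - sat[i])   # instantaneous bypass
        state.theta[i] = min(state.theta[i], sat[i])
        drain = swcon[i] * max(0.0, state.theta[i] - dul[i])
        state.theta[i] -= drain
        flux = drain * th[i] + surplus * th[i]
    deep_drainage = flux

    if infiltrated > 0:
        state.sumes1 = max(0.0, state.sumes1 - infiltrated)
        if state.sumes1 < profile.u_mm:
            state.t2 = 0

    state.runoff_mm += runoff
    state.drain_mm += deep_drainage
    return runoff, deep_drainage


def potential_evapotranspiration(tmax: float, tmin: float, radn: float,
                                 albedo: float = 0.13) -> float:
    """Priestley-Taylor equilibrium evaporation, mm d-1.

    Equilibrium term uses the weighted mean temperature 0.75 Tmax +
    0.25 Tmin; the multiplier rises above 1.1 on very hot days (> 35 degC)
    to reflect advective demand.
    """
    wt_temp = 0.75 * tmax + 0.25 * tmin
    eeq = radn * 23.8846 * (0.000204 - 0.000183 * albedo) * (wt_temp + 29.0)
    fac = PT_COEFF if tmax <= 35.0 else PT_COEFF + 0.05 * (tmax - 35.0)
    return max(0.0, eeq * fac)


def soil_evaporation_step(
    state: SoilWaterState, profile: SoilProfile, eos: float
) -> float:
    """One day of two-stage soil evaporation; returns actual Es (mm).

    Stage 1 (energy-limited) proceeds at the potential rate until the
    cumulative total since rewetting reaches U; stage 2 then supplies
    cona x (sqrt(t) - sqrt(t-1)) mm on day t.  Water is removed from the
    surface layer, never below its air-dry content.  Stage-2 time advances
    even on zero-demand days (drying is time-, not demand-, driven there).
    """
    if eos < 0:
        raise ValueError("eos must be non-negative")
    if state.sumes1 < profile.u_mm:
        es = min(eos, profile.u_mm - state.sumes1)
        state.sumes1 += es
    else:
        state.t2 += 1
        cap = profile.cona * (np.sqrt(state.t2) - np.sqrt(state.t2 - 1))
        es = min(eos, cap)

    th0 = profile.thickness[0]
    max_es = max(0.0, (state.theta[0] - profile.airdry[0]) * th0)
    es = min(es, max_es)
    state.theta[0] -= es / th0
    state.es_mm += es
    return es


def water_supply(state: SoilWaterState, profile: SoilProfile,
                 root_depth_mm: float) -> np.ndarray:
    """Potential daily root extraction per layer: KL x available x rooted
    fraction, mm."""
    frac = profile.layer_fractions(root_depth_mm)
    return (profile.kl * np.clip(state.theta - profile.ll, 0.0, None)
            * profile.thickness * frac)


def extract_transpiration(
    state: SoilWaterState, profile: SoilProfile, demand: float,
    root_depth_mm: float,
) -> float:
    """Remove min(demand, supply) from rooted layers, proportionally to each
    layer's supply; returns actual uptake (mm).  Mutates ``state``."""
    if demand < 0:
        raise ValueError("demand must be non-negative")
    supply = water_supply(state, profile, root_depth_mm)
    total = float(supply.sum())
    if total <= 0.0 or demand == 0.0:
        return 0.0
    uptake = min(demand, total)
    state.theta -= (uptake * supply / total) / profile.thickness
    return uptake
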