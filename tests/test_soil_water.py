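"""Cascading water balance: PAWC, infiltration/drainage, two-stage
evaporation and root extraction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mulchwheat.soil import (
    SoilLayer,
    SoilProfile,
    SoilWaterState,
    available_water,
    compute_pawc,
    extract_transpiration,
    infiltrate_and_drain,
    initialize_profile_water,
    potential_evapotranspiration,
    soil_evaporation_step,
    soil_water_deficit,
    water_supply,
)


def brute_force_pawc(profile, depth_mm):
    """Millimetre-by-millimetre integration oracle."""
    total = 0.0
    bottoms = np.cumsum([l.thickness_mm for l in profile.layers])
    tops = bottoms - [l.thickness_mm for l in profile.layers]
    for mm in range(int(depth_mm)):
        for top, bot, layer in zip(tops, bottoms, profile.layers):
            if top <= mm < bot:
                total += layer.dul - layer.ll
                break
    return total


class TestPawc:
    def test_single_layer_arithmetic(self):
        layer = SoilLayer(100.0, ll=0.10, dul=0.30, sat=0.40, bd=1.5,
                          swcon=0.5, kl=0.05)
        prof = SoilProfile([layer], u_mm=10, cona=2)
        assert compute_pawc(prof, 100.0) == pytest.approx(20.0)

    @pytest.mark.parametrize("soil_fixture, depth, expected", [
        ("sandy_loam", 600.0, 109.5),
        ("clay_loam", 600.0, 127.5),
        ("sandy_loam", 1800.0, 289.5),
        ("clay_loam", 1800.0, 334.5),
        ("sandy_loam", 450.0, 84.0),   # pro-rated mid-layer depth
    ])
    def test_matches_brute_force(self, request, soil_fixture, depth, expected):
        prof = request.getfixturevalue(soil_fixture)
        assert compute_pawc(prof, depth) == pytest.approx(expected, abs=1e-9)
        assert compute_pawc(prof, depth) == pytest.approx(
            brute_force_pawc(prof, depth), abs=1e-9)

    def test_negative_depth_rejected(self, sandy_loam):
        with pytest.raises(ValueError):
            compute_pawc(sandy_loam, -5.0)


class TestInitialWater:
    def test_full_profile_at_dul(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        assert available_water(state, sandy_loam) == pytest.approx(
            compute_pawc(sandy_loam), abs=1e-9)

    def test_counters_zeroed(self, clay_loam):
        state = initialize_profile_water(clay_loam)
        assert state.sumes1 == 0 and state.t2 == 0 and state.es_mm == 0

    def test_top_depth_beyond_profile_rejected(self, sandy_loam):
        with pytest.raises(ValueError):
            initialize_profile_water(sandy_loam, top_depth_mm=5000.0)


class TestDeficit:
    def test_zero_at_dul(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        assert soil_water_deficit(state, sandy_loam, 600.0) == pytest.approx(0.0)

    def test_equals_pawc_at_lower_limit(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        state.theta = sandy_loam.ll.copy()
        assert soil_water_deficit(state, sandy_loam, 600.0) == pytest.approx(
            compute_pawc(sandy_loam, 600.0))

    def test_partial_depletion_arithmetic(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        state.theta[0] -= 0.05  # one 150 mm layer 0.05 below DUL
        assert soil_water_deficit(state, sandy_loam, 600.0) == pytest.approx(7.5)


class TestInfiltrateAndDrain:
    def test_no_water_no_change(self, sandy_loam):
        state = initialize_profile_water(sandy_loam)
        theta0 = state.theta.copy()
        runoff, drain = infiltrate_and_drain(state, sandy_loam, 0.0)
        assert runoff == 0 and drain == 0
        np.testing.assert_allclose(state.theta, theta0)

    def test_swcon_drainage_hand_oracle(self, single_layer_profile):
        # 100 mm layer at DUL + 0.10 with SWCON = 0.5 sheds 5 mm in a day
        state = SoilWaterState(theta=np.array([0.30]))
        _, drain = infiltrate_and_drain(state, single_layer_profile, 0.0)
        assert drain == pytest.approx(5.0)
        assert state.theta[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("soil_fixture", ["sandy_loam", "clay_loam"])
    def test_record_storm_generates_no_runoff(self, request, soil_fixture):
        """A 102 mm day on a wetted profile stays within the 100 mm bund."""
        prof = request.getfixturevalue(soil_fixture)
        state = initialize_profile_water(prof, top_fraction=1.0)
        runoff, _ = infiltrate_and_drain(state, prof, 102.0)
        assert runoff == 0.0

    def test_runoff_above_bund_when_saturated(self, single_layer_profile):
        state = SoilWaterState(theta=np.array([0.40]))  # at SAT
        runoff, _ = infiltrate_and_drain(state, single_layer_profile, 250.0)
        assert state.pond_mm == pytest.approx(100.0)  # bund-full pond
        assert runoff > 0

    def test_ponded_water_infiltrates_next_day(self, single_layer_profile):
        state = SoilWaterState(theta=np.array([0.40]))
        infiltrate_and_drain(state, single_layer_profile, 150.0)
        assert state.pond_mm > 0
        # drainage frees pore space; the pond should drain into it next day
        infiltrate_and_drain(state, single_layer_profile, 0.0)
        assert state.pond_mm < 100.0

    @given(water=st.floats(0.0, 200.0),
           fill=st.floats(0.0, 1.0))
    def test_mass_conservation(self, sandy_loam, water, fill):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        state.theta = sandy_loam.ll + fill * (sandy_loam.sat - sandy_loam.ll)
        before = state.storage_mm(sandy_loam)
        runoff, drain = infiltrate_and_drain(state, sandy_loam, water)
        after = state.storage_mm(sandy_loam)
        assert water + before == pytest.approx(after + runoff + drain, abs=1e-9)
        assert (state.theta <= sandy_loam.sat + 1e-12).all()

    def test_negative_input_rejected(self, sandy_loam):
        state = initialize_profile_water(sandy_loam)
        with pytest.raises(ValueError):
            infiltrate_and_drain(state, sandy_loam, -1.0)


class TestPotentialEvapotranspiration:
    def test_zero_radiation_zero_eo(self):
        assert potential_evapotranspiration(25.0, 10.0, 0.0) == 0.0

    def test_linear_in_radiation(self):
        one = potential_evapotranspiration(25.0, 10.0, 8.0)
        two = potential_evapotranspiration(25.0, 10.0, 16.0)
        assert two == pytest.approx(2 * one)

    def test_increases_with_temperature(self):
        cool = potential_evapotranspiration(15.0, 5.0, 10.0)
        warm = potential_evapotranspiration(30.0, 18.0, 10.0)
        assert warm > cool

    def test_typical_april_day_plausible(self):
        # April normals: pan evaporation ~227 mm/month = 7.6 mm/day
        eo = potential_evapotranspiration(32.3, 21.4, 16.4)
        assert 4.0 <= eo <= 9.0


class TestSoilEvaporation:
    def test_stage1_at_potential(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        es = soil_evaporation_step(state, sandy_loam, 6.0)
        assert es == pytest.approx(6.0)
        assert state.sumes1 == pytest.approx(6.0)

    def test_stage1_capacity_then_stage2_decay(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        soil_evaporation_step(state, sandy_loam, 6.0)
        es = soil_evaporation_step(state, sandy_loam, 6.0)
        assert es == pytest.approx(4.0)  # only 4 mm of U = 10 remains
        # stage 2: day t supplies cona x (sqrt(t) - sqrt(t-1))
        cona = sandy_loam.cona
        for t in range(1, 5):
            es = soil_evaporation_step(state, sandy_loam, 10.0)
            assert es == pytest.approx(cona * (np.sqrt(t) - np.sqrt(t - 1)),
                                       abs=1e-9)
        assert es <= 0.54  # day 4: 2 x (sqrt 4 - sqrt 3) ~ 0.536

    def test_rewetting_resets_stage1(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        for _ in range(4):
            soil_evaporation_step(state, sandy_loam, 5.0)
        assert state.t2 > 0
        infiltrate_and_drain(state, sandy_loam, 30.0)  # >= stage-1 deficit
        assert state.sumes1 == 0.0 and state.t2 == 0
        es = soil_evaporation_step(state, sandy_loam, 5.0)
        assert es == pytest.approx(5.0)  # back at the stage-1 rate

    def test_cumulative_es_never_exceeds_cumulative_demand(self, clay_loam):
        state = initialize_profile_water(clay_loam, top_fraction=1.0)
        rng = np.random.default_rng(0)
        cum_eos = cum_es = 0.0
        for eos in rng.uniform(0, 6, size=60):
            cum_eos += eos
            cum_es += soil_evaporation_step(state, clay_loam, float(eos))
            assert cum_es <= cum_eos + 1e-9

    def test_never_below_airdry(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        for _ in range(400):
            soil_evaporation_step(state, sandy_loam, 8.0)
        assert state.theta[0] >= sandy_loam.airdry[0] - 1e-12

    def test_zero_demand_zero_es(self, sandy_loam):
        state = initialize_profile_water(sandy_loam)
        assert soil_evaporation_step(state, sandy_loam, 0.0) == 0.0


class TestRootExtraction:
    def test_no_water_no_uptake(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        state.theta = sandy_loam.ll.copy()
        assert extract_transpiration(state, sandy_loam, 5.0, 1800.0) == 0.0

    def test_demand_met_when_supply_ample(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        assert extract_transpiration(state, sandy_loam, 2.0, 1800.0) == \
            pytest.approx(2.0)

    def test_supply_limited_split_proportional(self):
        # two layers engineered to supply 3 mm and 1 mm per day
        layers = [
            SoilLayer(1000.0, ll=0.10, dul=0.40, sat=0.50, bd=1.5,
                      swcon=0.5, kl=0.01),   # 0.01 x 0.30 x 1000 = 3 mm
            SoilLayer(1000.0, ll=0.10, dul=0.20, sat=0.50, bd=1.5,
                      swcon=0.5, kl=0.01),   # 0.01 x 0.10 x 1000 = 1 mm
        ]
        prof = SoilProfile(layers, u_mm=10, cona=2)
        state = SoilWaterState(theta=prof.dul.copy())
        supply = water_supply(state, prof, 2000.0)
        np.testing.assert_allclose(supply, [3.0, 1.0])
        uptake = extract_transpiration(state, prof, 8.0, 2000.0)
        assert uptake == pytest.approx(4.0)
        np.testing.assert_allclose(prof.dul - state.theta, [0.003, 0.001])

    def test_rooted_fraction_prorated(self, sandy_loam):
        state = initialize_profile_water(sandy_loam, top_fraction=1.0)
        shallow = water_supply(state, sandy_loam, 300.0).sum()
        deep = water_supply(state, sandy_loam, 1800.0).sum()
        assert 0 < shallow < deep
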