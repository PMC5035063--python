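"""Shared fixtures.

The multi-year scenario runs used by the acceptance tests are expensive
(~1000 simulated seasons each) and session-scoped so several tests can
share one run.  Unit tests use small purpose-built profiles and short
weather series instead.
"""

import numpy as np
import pytest
from hypothesis import settings

from mulchwheat import (
    ScenarioConfig,
    generate_synthetic_weather,
    load_cultivar,
    load_soil,
    ludhiana_normals,
    run_scenario,
)
from mulchwheat.soil import SoilLayer, SoilProfile

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: seed for all stochastic fixtures
SEED = 1
#: years in the long study-condition runs (the published study used 40)
STUDY_YEARS = 40


@pytest.fixture(scope="session")
def sandy_loam():
    return load_soil("sandy_loam")


@pytest.fixture(scope="session")
def clay_loam():
    return load_soil("clay_loam")


@pytest.fixture(scope="session")
def bare_cultivar():
    return load_cultivar("pbw343_bare")


@pytest.fixture(scope="session")
def mulch_cultivar():
    return load_cultivar("pbw343_mulch")


@pytest.fixture(scope="session")
def normals():
    return ludhiana_normals()


@pytest.fixture(scope="session")
def weather3(normals):
    """Three calendar years of synthetic weather for short engine tests."""
    return generate_synthetic_weather(normals, 3, seed=SEED)


@pytest.fixture(scope="session")
def single_layer_profile():
    """One 100 mm layer with simple round numbers for hand oracles."""
    layer = SoilLayer(thickness_mm=100.0, ll=0.10, dul=0.20, sat=0.40,
                      bd=1.5, swcon=0.5, kl=0.05)
    return SoilProfile(layers=[layer], u_mm=6.0, cona=3.5, bund_mm=100.0,
                       name="single")


@pytest.fixture(scope="session")
def scenario2_results():
    """Mulch x sowing date at 50% SWD, both soils, 40 synthetic years."""
    return run_scenario(ScenarioConfig.for_scenario(2, years=STUDY_YEARS,
                                                    seed=SEED))


@pytest.fixture(scope="session")
def scenario3_results():
    """Irrigation threshold x mulch, 7 Nov sowing, both soils, 40 years."""
    return run_scenario(ScenarioConfig.for_scenario(3, years=STUDY_YEARS,
                                                    seed=SEED))


@pytest.fixture(scope="session")
def potential_vs_scheduled_results():
    """Potential vs 50% SWD for the 10 Nov sowing, both soils, 40 years."""
    cfg = ScenarioConfig.for_scenario(1, years=STUDY_YEARS, seed=SEED,
                                      sowing_dates=((11, 10),))
    return run_scenario(cfg)
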