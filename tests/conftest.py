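import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from savgsa import (
    ScenarioConfig,
    SpeciesModel,
    SuitabilityCurve,
    generate_hydrology,
)


@pytest.fixture
def ramp_curve():
    """Descending ramp: si = 1 at x=0, 0 at x=10."""
    return SuitabilityCurve("salinity", ((0.0, 1.0), (10.0, 0.0)))


@pytest.fixture
def toy_species():
    """Single-ADBL toy model with hand-friendly breakpoints."""
    return SpeciesModel(
        name="toy",
        salinity_curve=SuitabilityCurve("salinity", ((0, 0), (5, 1), (20, 1), (30, 0))),
        temperature_curve=SuitabilityCurve("temperature", ((10, 0), (20, 1), (30, 1), (35, 0))),
        adbl_curves=(SuitabilityCurve("adbl", ((0, 0), (400, 1), (1000, 1))),),
    )


@pytest.fixture
def dual_adbl_species():
    """Two-ADBL-curve toy model (tape-grass-like) with threshold 10 PSU."""
    return SpeciesModel(
        name="toy2",
        salinity_curve=SuitabilityCurve("salinity", ((0, 1), (15, 0))),
        temperature_curve=SuitabilityCurve("temperature", ((10, 0), (20, 1), (35, 0))),
        adbl_curves=(
            SuitabilityCurve("adbl", ((0, 0), (300, 1), (1000, 1))),
            SuitabilityCurve("adbl", ((0, 0), (600, 1), (1000, 1))),
        ),
        adbl_salinity_threshold=10.0,
    )


@pytest.fixture
def tiny_scenario():
    return ScenarioConfig(
        nrows=4, ncols=4, start=(1999, 1), end=(1999, 12), slr_total=0.0, rng_seed=11
    )


@pytest.fixture
def tiny_grid(tiny_scenario):
    return generate_hydrology(tiny_scenario)
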