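import numpy as np
import pytest

from ondatra import DeltaScenario, FloodKernel, HexGrid, WalkParams, generate_atlas
from ondatra.population import DemographyParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def grid10():
    return HexGrid(10, 10, 60.0)


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small, fast synthetic delta reused across the demographic tests."""
    return DeltaScenario(
        n_rows=40, n_per_row=40, n_years=10, flood_years=(3,),
        flood_expansion=2.0, n_lakes=3, n_isolated=1,
        lake_radius_px=(4, 6), isolated_radius_px=(3, 4), seed=7,
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_scenario):
    return generate_atlas(tiny_scenario)


@pytest.fixture(scope="session")
def default_params():
    return DemographyParams(), WalkParams(), FloodKernel()
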