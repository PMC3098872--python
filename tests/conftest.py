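import numpy as np
import pytest

from gatekin.grids import ConfigGrid
from gatekin.landscape import LandscapeParams, synthetic_landscape
from gatekin.prob_evolution import SolverConfig


@pytest.fixture(scope="session")
def default_grid() -> ConfigGrid:
    return ConfigGrid.default()


@pytest.fixture(scope="session")
def default_params() -> LandscapeParams:
    return LandscapeParams()


@pytest.fixture(scope="session")
def landscape_hold(default_params, default_grid):
    """Default landscape at the -100 mV holding potential."""
    return synthetic_landscape(default_params, default_grid, -100.0)


@pytest.fixture(scope="session")
def landscape_test(default_params, default_grid):
    """Default landscape at the +60 mV test potential."""
    return synthetic_landscape(default_params, default_grid, 60.0)


@pytest.fixture(scope="session")
def solver() -> SolverConfig:
    return SolverConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def coarse_grid() -> ConfigGrid:
    """Half-resolution grid for tests that need long integrations."""
    return ConfigGrid(
        z_values=np.round(np.arange(-35, 16) * 0.4, 10),
        phi_values=np.round(np.arange(-10, 11) * 0.1, 10),
    )
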