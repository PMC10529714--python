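import numpy as np
import pytest

from coldspot.config import default_config
from coldspot.properties import ThermoProps
from coldspot.solver import Geometry, Grid, simulate

#: Default-scenario effective properties (direct route).
DEFAULT_PROPS = ThermoProps(rho=1064.5, cp=3535.5, k=0.47)
DEFAULT_GEOM = Geometry.from_full(0.085, 0.54)
T0_DEFAULT = 280.65

COARSE_GRID = Grid(10, 16)
FIT_GRID = Grid(12, 24)


@pytest.fixture(scope="session")
def default_cfg():
    return default_config()


@pytest.fixture(scope="session")
def default_run(default_cfg):
    """Full default-scenario run at the production grid (shared, ~6 s)."""
    return simulate(
        default_cfg.build_geometry(),
        default_cfg.build_props(),
        default_cfg.build_schedule(),
        default_cfg.initial_temperature_K,
        default_cfg.build_grid(),
        snapshot_times=(20000.0,),
    )


@pytest.fixture
def coarse_grid():
    return COARSE_GRID
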