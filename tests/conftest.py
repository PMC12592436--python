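import numpy as np
import pytest

from cryolight.engine import RtmConfig, run_rtm
from cryolight.forcing import Grid1x1
from cryolight.synthetic import SyntheticForcingConfig, generate_synthetic_forcing


@pytest.fixture(scope="session")
def coarse_grid():
    """Reduced polar domain: 3-degree latitude by 30-degree longitude steps."""
    return Grid1x1(lat=np.arange(61.0, 85.0, 3.0), lon=np.arange(0.0, 360.0, 30.0))


@pytest.fixture(scope="session")
def forcing_2yr(coarse_grid):
    cfg = SyntheticForcingConfig(start_year=1979, end_year=1980, seed=7, grid=coarse_grid)
    return generate_synthetic_forcing(cfg)


@pytest.fixture(scope="session")
def forcing_10yr(coarse_grid):
    """Decade-long synthetic run used by the sensitivity-direction suite."""
    cfg = SyntheticForcingConfig(start_year=1979, end_year=1988, seed=7, grid=coarse_grid)
    return generate_synthetic_forcing(cfg)


@pytest.fixture(scope="session")
def light_2yr(forcing_2yr):
    return run_rtm(forcing_2yr, RtmConfig())


@pytest.fixture(scope="session")
def light_10yr_base(forcing_10yr):
    return run_rtm(forcing_10yr, RtmConfig())
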