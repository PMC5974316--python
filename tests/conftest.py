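import numpy as np
import pytest

from smlvoc import (
    PhotochemConfig,
    SynthConfig,
    make_grid,
    make_npp,
    make_uv,
    make_wind,
    potential_field,
)


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def synth_cfg():
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def uv(synth_cfg, grid):
    return make_uv(synth_cfg, grid)


@pytest.fixture(scope="session")
def wind(synth_cfg, grid):
    return make_wind(synth_cfg, grid)


@pytest.fixture(scope="session")
def npp(synth_cfg, grid):
    return make_npp(synth_cfg, grid)


@pytest.fixture(scope="session")
def potential13(uv, wind, npp):
    return potential_field(uv, wind, npp, PhotochemConfig(wind_limit=13.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180529)
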