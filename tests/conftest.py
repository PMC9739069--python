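import numpy as np
import pytest

from camarkov import LandCoverGrid, generate_scenario
from camarkov.raster import DEFAULT_LEGEND


@pytest.fixture(scope="session")
def scenario_small():
    """Compact synthetic study region shared across fast tests."""
    return generate_scenario(size=64, seed=7)


@pytest.fixture(scope="session")
def scenario_default():
    """Default-size (256 x 256) synthetic study region."""
    return generate_scenario(size=256, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_grid(rng, shape=(20, 20), classes=(1, 2, 3), cell_size_m=500.0,
                nodata_frac=0.0):
    codes = rng.choice(classes, size=shape).astype(np.int32)
    if nodata_frac > 0:
        codes[rng.random(shape) < nodata_frac] = 0
    return LandCoverGrid(codes, cell_size_m=cell_size_m,
                         legend={k: DEFAULT_LEGEND[k] for k in DEFAULT_LEGEND})
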