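import numpy as np
import pytest

from pmaa import CArmGeometry


@pytest.fixture(scope="session")
def geom() -> CArmGeometry:
    """Default mobile-C-arm geometry."""
    return CArmGeometry()


@pytest.fixture(scope="session")
def coarse_geom() -> CArmGeometry:
    """Same system with coarser candidate grids, for map-level tests."""
    return CArmGeometry(theta_step=10.0, delta_step=6.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
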