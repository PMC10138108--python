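import numpy as np
import pytest

from sparsect import ScanGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fan_desk_geometry():
    """Sparse-view fan geometry at desk scale: 180 views, clinical channel density."""
    return ScanGeometry("fan_equiangular", n_views=180, n_channels=224)


@pytest.fixture(scope="session")
def parallel_small_geometry():
    return ScanGeometry("parallel", n_views=60, n_channels=112)
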