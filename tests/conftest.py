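import numpy as np
import pytest

from trnatrack import CellGeometry, ImagingConfig, TrackingConfig


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()  # 3 x 1 um spherocylinder


@pytest.fixture(scope="session")
def imaging():
    return ImagingConfig()


@pytest.fixture(scope="session")
def tracking():
    return TrackingConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
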