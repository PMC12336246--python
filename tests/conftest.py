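import numpy as np
import pytest

from compresscan.continuum_model import TissueModel
from compresscan.fabric_mechanics import FabricProperties


@pytest.fixture
def fabric_sample_1():
    return FabricProperties(Ex=2230.0, Ey=2460.0, Gxy=657.40, vxy=0.13, label="sample-1")


@pytest.fixture
def fabric_sample_4():
    return FabricProperties(Ex=4350.0, Ey=3790.0, Gxy=661.26, vxy=0.16, label="sample-4")


@pytest.fixture
def tissue():
    return TissueModel(Es=15000.0, vs=0.3)


@pytest.fixture
def circle_points():
    """720 points on a 50 mm circle centered at (128, 128)."""
    theta = np.arange(720) * (2 * np.pi / 720)
    x = 128.0 - 50.0 * np.sin(theta)
    y = 128.0 + 50.0 * np.cos(theta)
    return np.column_stack([x, y])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
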