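import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drquad import FundusFrame

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def right_frame() -> FundusFrame:
    """Right eye: disc on the image right, fovea at the field center (9 um/px)."""
    return FundusFrame("right-eye", 1440, 960, 719.5, 479.5, 1219.5, 449.5)


@pytest.fixture
def left_frame() -> FundusFrame:
    return FundusFrame("left-eye", 1440, 960, 719.5, 479.5, 219.5, 449.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
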