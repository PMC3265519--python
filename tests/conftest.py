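import numpy as np
import pytest

from smlm.calibrate import default_astigmatic_curve
from smlm.simulate import CameraModel


@pytest.fixture(scope="session")
def curve():
    return default_astigmatic_curve()


@pytest.fixture(scope="session")
def quiet_camera():
    """Noise-free camera for exact round-trip checks."""
    return CameraModel(background=0.0, offset=0.0, read_noise=0.0,
                       shot_noise=False)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
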