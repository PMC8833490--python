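import numpy as np
import pytest

from foxwatch import CameraModel, SimConfig, make_fixture


@pytest.fixture(scope="session")
def short_fixture():
    """10-minute two-camera bout with the default (moderate) noise model."""
    return make_fixture(SimConfig(duration_s=600.0, seed=42))


@pytest.fixture(scope="session")
def noiseless_fixture():
    """Noise-free two-camera bout: detections reproduce truth exactly."""
    cfg = SimConfig(
        duration_s=400.0,
        seed=7,
        cameras=[CameraModel(camera_id="cam1"), CameraModel(camera_id="cam2")],
    )
    return make_fixture(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
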