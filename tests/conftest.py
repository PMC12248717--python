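import numpy as np
import pytest

from savelight.calibration import calibrate
from savelight.synthetic_data import (
    SceneSpec,
    make_camera_model,
    make_reference_chart,
    simulate_capture,
    synth_endoscopy_scene,
)


@pytest.fixture(scope="session")
def chart():
    return make_reference_chart()


@pytest.fixture(scope="session")
def ideal_capture(chart):
    return simulate_capture(chart, make_camera_model("ideal"))


@pytest.fixture(scope="session")
def ideal_bundle(chart, ideal_capture):
    return calibrate(chart, ideal_capture)


@pytest.fixture(scope="session")
def realistic_capture(chart):
    return simulate_capture(chart, make_camera_model("realistic", seed=1))


@pytest.fixture(scope="session")
def realistic_bundle(chart, realistic_capture):
    return calibrate(chart, realistic_capture)


@pytest.fixture(scope="session")
def vessel_scene():
    return synth_endoscopy_scene(SceneSpec(height=48, width=48, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
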