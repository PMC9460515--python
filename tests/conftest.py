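import numpy as np
import pytest

from tremorsim.sensor_model import InertialRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_static_record(fs: float = 1000.0, duration: float = 10.0,
                       accel_z: float = 1.0) -> InertialRecord:
    """Perfectly still sensor: +1 g on z, zero rates, constant field."""
    n = int(round(duration * fs))
    accel = np.zeros((3, n))
    accel[2] = accel_z
    mag = np.tile(np.array([20.0, 5.0, -45.0])[:, None], (1, n))
    return InertialRecord(fs, accel, np.zeros((3, n)), mag)


@pytest.fixture
def static_record():
    return make_static_record()
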