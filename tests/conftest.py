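import numpy as np
import pytest

from walkrec import synth
from walkrec.imu_io import ImuSeries


@pytest.fixture
def static_series():
    """2 s of a face-up resting device: a = (0, 0, g), ω = 0."""
    n = 200
    return ImuSeries(
        t=np.arange(n) / 100.0,
        a=np.tile([0.0, 0.0, 9.81], (n, 1)),
        omega=np.zeros((n, 3)),
        rate_hz=100.0,
    )


@pytest.fixture(scope="session")
def walking_record():
    """Seeded 10 s walking trace at a known 2 Hz step frequency."""
    return synth.gen_walking(10.0, synth.GaitParams(step_freq_hz=2.0), seed=3)


@pytest.fixture(scope="session")
def gesture_record():
    return synth.gen_gesture(10.0, synth.GaitParams(), seed=3)


@pytest.fixture(scope="session")
def toy_patterns():
    """Six scalar 250-sample patterns forming two tight shape groups.

    Group A: 2 Hz tones (walking-like); group B: slow 0.5 Hz drifts.
    """
    t = np.arange(250) / 100.0
    rng = np.random.default_rng(7)
    a = [np.sin(2 * np.pi * 2.0 * t + ph) * 3.0 + rng.normal(0, 0.05, 250)
         for ph in (0.0, 0.4, 0.8)]
    b = [np.sin(2 * np.pi * 0.5 * t + ph) * 3.0 + rng.normal(0, 0.05, 250)
         for ph in (0.0, 0.5, 1.0)]
    X = np.stack(a + b)
    y = np.array([1, 1, 1, 0, 0, 0])
    return X, y
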