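import numpy as np
import pytest

from csdflow.io import Movie, TimeWindow, Trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_movie(rng):
    """10-frame 8x8 uint16 movie at 10 Hz."""
    data = rng.integers(100, 4000, size=(10, 8, 8), dtype=np.uint16)
    return Movie(data=data, frame_rate_hz=10.0, pixel_pitch_mm=0.2)


@pytest.fixture
def noise_trace(rng):
    """10-min pure-noise dF/F trace at 10 Hz with a pre-KCl segment."""
    vals = rng.normal(0.0, 0.01, size=7200)
    return Trace(values=vals, rate_hz=10.0, t0_s=-120.0, unit="dff")


@pytest.fixture
def baseline_window():
    return TimeWindow(-60.0, -20.0)
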