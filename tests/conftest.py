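import numpy as np
import pytest

from fingertap import Demographics, HandPoseSeries, TapSpec
from fingertap.signal import PeakSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def demographics():
    return Demographics(age=68, sex="male")


def make_pose_series(coords_fn=None, n_frames=10, fps=60.0):
    """Small pose series with wrist at origin and middle MCP one unit away."""
    coords = np.zeros((n_frames, 21, 3))
    coords[:, 9, 1] = 1.0  # middle MCP
    coords[:, 4, 0] = 0.3  # thumb tip
    coords[:, 8, 0] = 0.3
    coords[:, 8, 1] = 0.5  # index tip: distance 0.5 from thumb
    if coords_fn is not None:
        coords_fn(coords)
    return HandPoseSeries(coords=coords, fps=fps)


def make_peaks(amplitudes, dt=0.4, fps=60.0):
    """PeakSet with uniform spacing ``dt`` seconds."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = amplitudes.size
    times = np.arange(n) * dt
    indices = np.round(times * fps).astype(int)
    indices = np.maximum(indices, np.arange(n))  # keep strictly increasing
    return PeakSet(indices=indices, amplitudes=amplitudes, fps=fps, times=times)


@pytest.fixture
def noiseless_spec():
    return TapSpec(
        duration=10.0,
        fps=60.0,
        rate=3.0,
        base_amplitude=1.4,
        decrement=(0.5, 0.0, -0.04),
        noise_sd=0.0,
        tremor=(5.0, 0.0),
        seed=1,
    )
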