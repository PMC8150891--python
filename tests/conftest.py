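import numpy as np
import pytest

from eegyaw.config import RunConfig
from eegyaw.synth import Recording


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_recording(data: np.ndarray, fs: float = 500.0) -> Recording:
    """Wrap a (3, n) array as a Recording with the standard montage."""
    return Recording(channels=("O1", "O2", "CZ"), fs=fs, data=data)


@pytest.fixture()
def sine_recording():
    """10 s of a pure tone per factory call: freq -> Recording."""

    def _make(freq: float, amplitude: float = 1.0, fs: float = 500.0, dur: float = 10.0):
        t = np.arange(int(dur * fs)) / fs
        x = amplitude * np.sin(2 * np.pi * freq * t)
        return make_recording(np.tile(x, (3, 1)), fs)

    return _make
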