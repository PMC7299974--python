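import numpy as np
import pytest

from circafeed import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def config():
    return SimConfig(seed=7)


def cosine_series(times, mesor, amplitude, acrophase, period=24.0):
    t = np.asarray(times, dtype=float)
    return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase) / period)
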