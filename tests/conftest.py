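import numpy as np
import pytest

from phasecrit.phase import SampledSignal


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def tone():
    """Pure 5 Hz cosine sampled at 600 Hz."""
    fs = 600.0
    t = np.arange(6000) / fs
    return SampledSignal(values=np.cos(2 * np.pi * 5 * t), sampling_rate=fs, label="tone5")


def make_signal(values, fs=600.0, label=""):
    return SampledSignal(values=np.asarray(values, dtype=float), sampling_rate=fs, label=label)
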