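import numpy as np
import pytest

from phonoid.signal_metrics import Signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq: float, fs: float = 1000.0, duration: float = 2.0, amp: float = 1.0) -> Signal:
    t = np.arange(round(duration * fs)) / fs
    return Signal(amp * np.sin(2 * np.pi * freq * t), fs)


def make_noise(fs: float = 1000.0, n: int = 4096, sd: float = 1.0, seed: int = 0) -> Signal:
    r = np.random.default_rng(seed)
    return Signal(r.normal(0.0, sd, n), fs)
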