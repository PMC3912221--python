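import numpy as np
import pytest

from megnet import BandDefinition, EpochArray


@pytest.fixture
def alpha_band() -> BandDefinition:
    return BandDefinition("alpha", 8.0, 13.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def sinusoid_epoch(freq: float, fs: float = 512.0, n: int = 4096, phase: float = 0.0) -> EpochArray:
    """Single-channel cosine; the default fs puts integer frequencies on the
    DFT grid (bin spacing 0.125 Hz), so a pure tone occupies a single bin."""
    t = np.arange(n) / fs
    return EpochArray(np.cos(2 * np.pi * freq * t + phase)[None, :], fs)


def random_symmetric(n: int, seed: int) -> np.ndarray:
    r = np.random.default_rng(seed)
    w = np.triu(r.random((n, n)), 1)
    return w + w.T
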