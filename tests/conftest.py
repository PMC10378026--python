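import numpy as np
import pytest

from petd.ordinal import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20230719)


def tiled_sine(period: int, n_periods: int, fs: float = 250.0) -> TimeSeries:
    """A discretely periodic sine: one period tiled, so values repeat
    bit-exactly cycle to cycle (no floating-point phase drift)."""
    one = np.sin(2 * np.pi * np.arange(period) / period)
    return TimeSeries(np.tile(one, n_periods), fs)


@pytest.fixture
def sine20():
    return tiled_sine(20, 200)
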