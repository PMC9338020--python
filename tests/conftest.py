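import numpy as np
import pytest

from orgephys.io import LFPSet, SpikeTrainSet


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trains(times_by_unit: dict, duration: float, positions=None) -> SpikeTrainSet:
    ids = np.asarray(sorted(times_by_unit), dtype=np.int64)
    return SpikeTrainSet(
        ids,
        {int(u): np.asarray(times_by_unit[u], dtype=np.float64) for u in ids},
        positions,
        duration,
    )


@pytest.fixture()
def poisson_pair(rng):
    """Two independent 2 Hz Poisson trains over 300 s."""
    def draw():
        t = np.cumsum(rng.exponential(0.5, 900))
        return t[t < 300.0]
    return draw(), draw()


@pytest.fixture()
def sine_lfp():
    """Four-channel 6 Hz test LFP: two in-phase, one quadrature, one noise."""
    fs = 1000.0
    t = np.arange(int(30 * fs)) / fs
    x = 20.0 * np.cos(2 * np.pi * 6.0 * t)
    q = 20.0 * np.sin(2 * np.pi * 6.0 * t)
    noise = np.random.default_rng(7).normal(0, 5.0, t.size)
    data = np.vstack([x, x, q, noise])
    pos = np.array([[0, 0], [100, 0], [0, 100], [500, 500]], dtype=float)
    return LFPSet(data, fs, pos, band="lfp")
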