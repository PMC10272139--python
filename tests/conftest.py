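import numpy as np
import pytest

from excitometry import synth
from excitometry.trace import Trace, Unit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_trace(rng):
    """1 s of unit Gaussian noise at 20 kHz."""
    return Trace(samples=rng.normal(0, 1, 20_000), fs=20_000.0, unit=Unit.uV)


def spaced_times(rng, n, lo, hi, min_gap_s):
    """n sorted times in [lo, hi] with pairwise gaps >= min_gap_s."""
    while True:
        t = np.sort(rng.uniform(lo, hi, n))
        if n < 2 or np.all(np.diff(t) >= min_gap_s):
            return t


@pytest.fixture
def planted_scene(rng):
    """An extracellular scene with 20 isolated spikes at known times."""
    times = spaced_times(rng, 20, 0.1, 9.9, 0.02)
    scene = synth.ExtracellularScene(
        seed=7, background_rate_hz=0.0, background_spike_times_s=tuple(times)
    )
    return synth.synth_extracellular(scene)
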