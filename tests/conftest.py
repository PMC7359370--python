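import numpy as np
import pytest

from caensemble.containers import EventTrain, TraceMatrix
from caensemble.simulate import default_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_traces(rng):
    """100 pure-noise cells at the acquisition rate (180 s at 20 fps)."""
    values = rng.normal(0.0, 1.0, (100, 3600))
    return TraceMatrix(values, 20.0, [f"c{i:03d}" for i in range(100)], "A1")


@pytest.fixture
def sim_config():
    return default_config(seed=7)


def make_train(cell_id, times, amp=4.0):
    times = np.asarray(times, dtype=float)
    return EventTrain(cell_id, times, np.full(times.size, amp))


@pytest.fixture
def poisson_trains(rng):
    """20 independent Poisson trains at 2 events/min over 180 s."""
    trains = []
    for i in range(20):
        n = rng.poisson(6)
        trains.append(make_train(f"c{i:03d}", np.sort(rng.random(n) * 180)))
    return trains
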