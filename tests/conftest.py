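import numpy as np
import pytest

from polarflux import SimConfig, Track


@pytest.fixture
def cfg():
    """Default simulation config with a fixed seed."""
    return SimConfig(seed=0)


@pytest.fixture
def ballistic_track():
    """Straight-line track at 5 µm/s along +x, 60 frames at 2 s."""
    t = np.arange(60) * 2.0
    pos = np.column_stack([5.0 * t, np.zeros_like(t)])
    return Track(id="ballistic", times=t, positions=pos)


def make_track(positions, dt=1.0, tid="t"):
    pos = np.asarray(positions, dtype=float)
    return Track(id=tid, times=np.arange(len(pos)) * dt, positions=pos)
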