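import numpy as np
import pytest

from neurophen import PoolGeometry, SwimTrial


@pytest.fixture
def pool() -> PoolGeometry:
    return PoolGeometry()


def make_trial(xy, dt=0.1, geometry=None, **kw):
    """Build a SwimTrial from a point sequence at uniform dt."""
    xy = np.asarray(xy, float)
    t = dt * np.arange(len(xy))
    return SwimTrial(
        trial_id=kw.pop("trial_id", "t"),
        animal_id=kw.pop("animal_id", "a"),
        t=t,
        x=xy[:, 0],
        y=xy[:, 1],
        geometry=geometry or PoolGeometry(),
        **kw,
    )
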