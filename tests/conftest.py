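import numpy as np
import pytest

from wormwatcher.activity import ActivityTrace
from wormwatcher.behavior import EpochSchedule


@pytest.fixture
def standard_schedule() -> EpochSchedule:
    """The twice-daily protocol: 30-min epochs, 10-s stimulus at 15 min."""
    return EpochSchedule.twice_daily(n_epochs=4)


def make_trace(well, interval_s, pair_starts, values) -> ActivityTrace:
    return ActivityTrace.from_pairs(well, interval_s, np.asarray(pair_starts, float),
                                    np.asarray(values))


@pytest.fixture
def trace_factory():
    return make_trace


def roi_mask_from(wmap, well, shape):
    mask = np.zeros(shape, dtype=bool)
    rows, cols = wmap.roi_indices(shape)[well]
    mask[rows, cols] = True
    return mask
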