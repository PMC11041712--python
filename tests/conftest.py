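import numpy as np
import pytest

from mirmem.behavior import ExplorationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_test_record(subject_id, new_time, familiar_times, novel_index=0, group=None):
    """Build a test-phase record with the novel object at ``novel_index``."""
    times = list(familiar_times)
    times.insert(novel_index, new_time)
    return ExplorationRecord(
        subject_id=subject_id,
        phase="test",
        object_times=tuple(times),
        novel_index=novel_index,
        group=group,
    )


@pytest.fixture
def record_factory():
    return make_test_record
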