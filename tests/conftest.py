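import numpy as np
import pytest

from omgpipe import generate_cohort, preprocess_for_statistics
from omgpipe.protocol import task_a


@pytest.fixture(scope="session")
def cohort3():
    """Three-participant cohort over the full three-task session."""
    return generate_cohort(n_participants=3, seed=1234)


@pytest.fixture(scope="session")
def recording(cohort3):
    return cohort3[0]


@pytest.fixture(scope="session")
def cohort_a6():
    """Six participants, Task A only (fast fixture for stats/ML tests)."""
    return generate_cohort(n_participants=6, protocols=(task_a(),), seed=99)


@pytest.fixture(scope="session")
def traces_events_a6(cohort_a6):
    return (
        [preprocess_for_statistics(r) for r in cohort_a6],
        [r.events for r in cohort_a6],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
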