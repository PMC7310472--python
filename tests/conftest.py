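import numpy as np
import pytest

from immunofrail.synthetic_data import (
    CohortSpec,
    cohort_frame,
    generate_cohort,
    true_count_matrix,
)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 289-participant cohort (145 men, 144 women), seed 0."""
    participants = generate_cohort(CohortSpec(seed=0))
    return participants, cohort_frame(participants), \
        true_count_matrix(participants)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
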