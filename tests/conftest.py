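import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from tempomem import (
    CohortConfig,
    default_scale,
    score_trials,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def scale():
    return default_scale()


@pytest.fixture(scope="session")
def sim_cohort(scale):
    """Reference-design cohort: 2 groups x 15 participants x 2 tasks x 7 trials."""
    return simulate_cohort(CohortConfig(seed=20160), scale)


@pytest.fixture(scope="session")
def scored_cohort(sim_cohort, scale):
    return score_trials(sim_cohort.trials, scale)
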