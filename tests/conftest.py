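import numpy as np
import pytest

from polygre.prs import attach_prs
from polygre.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 1200-subject study used by most unit tests."""
    return simulate_cohort(SimulationConfig(n_cases=600, n_controls=600, seed=3))


@pytest.fixture(scope="session")
def scored_cohort(small_dataset):
    return attach_prs(small_dataset.cohort, small_dataset.dosages,
                      small_dataset.panel)


@pytest.fixture(scope="session")
def study_dataset():
    """A paper-shaped study (~4500 subjects) for pipeline-level tests."""
    return simulate_cohort(SimulationConfig(n_cases=2500, n_controls=2000,
                                            seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
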