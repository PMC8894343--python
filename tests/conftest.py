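import numpy as np
import pytest

from sleepcog import SimulationConfig, generate_cohort, orient_tasks, transform_cognitive
from sleepcog.simulate import TASK_COLUMNS


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort, small enough for fast unit tests."""
    cfg = SimulationConfig(n_participants=4000, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def oriented_tasks(small_cohort):
    phenotype, _, _ = small_cohort
    return orient_tasks(transform_cognitive(phenotype))[TASK_COLUMNS]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
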