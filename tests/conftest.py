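import numpy as np
import pytest

from dehydrakit import CohortConfig, generate_cohort
from dehydrakit.scales import CDC_ITEMS, ObservationSet


@pytest.fixture
def rng():
    return np.random.default_rng(20251204)


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 300-child synthetic cohort shared across pipeline tests."""
    config = CohortConfig(n=300, seed=99)
    cohort, truth = generate_cohort(config)
    return config, cohort, truth


def random_observation(rng, missing_prob: float = 0.0) -> ObservationSet:
    levels = {}
    for item in CDC_ITEMS:
        if rng.random() < missing_prob:
            levels[item] = None
        else:
            levels[item] = int(rng.integers(0, 3))
    return ObservationSet(**levels)
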