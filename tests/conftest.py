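import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tradervote import (ObjectiveConfig, SubsetObjective, SyntheticSpec,
                        generate, min_max_normalize)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sep_table():
    """Small well-separated 2-class table with known informative columns."""
    table, truth = generate(SyntheticSpec(
        n_samples=60, n_features=8, n_informative=3, class_count=2,
        class_sep=8.0, noise_sd=1.0, seed=3))
    normed, _ = min_max_normalize(table)
    return normed, truth


@pytest.fixture(scope="session")
def sep_objective(sep_table):
    table, _ = sep_table
    return SubsetObjective(table, ObjectiveConfig(inner_folds=5, seed=7))


def low_index_fitness(cs):
    """Cheap stub fitness: fraction of the 3 lowest feature indices held."""
    return len({1, 2, 3} & set(int(v) for v in cs.indices)) / 3.0


@pytest.fixture
def stub_objective():
    return low_index_fitness


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
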