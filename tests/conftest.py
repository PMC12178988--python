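import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import ucross

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 10 markers each (L=20)."""
    return ucross.generate_map(2, 10, 80, seed=11)


@pytest.fixture(scope="session")
def small_pops(small_map):
    return ucross.generate_founder_populations(small_map, 40, seed=12)


@pytest.fixture(scope="session")
def small_effects(small_map):
    return ucross.generate_effects(
        small_map, ucross.default_architecture(small_map.n_markers), seed=13)


@pytest.fixture(scope="session")
def merged_pop(small_pops):
    p1, p2 = small_pops
    return ucross.Population.merge(p1, p2, "G0")


@pytest.fixture(scope="session")
def scaling(small_pops, small_effects):
    return ucross.ScalingStats.from_populations(list(small_pops),
                                                small_effects)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
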