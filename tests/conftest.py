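import numpy as np
import pytest

from opinionfield import ModelParams, Population, SocialNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_params():
    """Cheap configuration for fast unit tests."""
    return ModelParams(
        n_agents=40,
        mean_degree=4.0,
        max_steps=500,
        seed=7,
        record_every=10**9,
    )


@pytest.fixture
def path_graph():
    """0 - 1 - 2 path."""
    return SocialNetwork(3, [(0, 1), (1, 2)])


@pytest.fixture
def star_graph():
    """Centre 0 linked to 1..4."""
    return SocialNetwork(5, [(0, i) for i in range(1, 5)])


def population(opinions, attitudes=None, frozen=None):
    opinions = np.asarray(opinions, dtype=float)
    if attitudes is None:
        attitudes = np.zeros_like(opinions)
    return Population(opinions, np.asarray(attitudes, dtype=float), frozen)


@pytest.fixture
def make_population():
    return population
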