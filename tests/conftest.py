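import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from treelfa import (  # noqa: E402
    build_sim_tree,
    make_sim_topics,
    sim_hyperparams,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def sim_tree():
    return build_sim_tree()


@pytest.fixture(scope="session")
def correct_topics(sim_tree):
    return make_sim_topics(sim_tree, "correct_prior")


@pytest.fixture(scope="session")
def small_dataset(sim_tree, correct_topics):
    """One modest simulated dataset with its ground truth."""
    data, theta, Z = simulate_dataset(
        correct_topics, 1.0, 400, seed=7, code_ids=sim_tree.code_order
    )
    return data, theta, Z


@pytest.fixture(scope="session")
def sim_hyper():
    return sim_hyperparams(K=4, alpha=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
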