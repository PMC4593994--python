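import numpy as np
import pytest

from syndrive import GeneratorSpec, generate_network, paper_fixture


@pytest.fixture(scope="session")
def fig11():
    return paper_fixture("fig11")


@pytest.fixture(scope="session")
def eq126():
    return paper_fixture("eq126")


@pytest.fixture(scope="session")
def eq127():
    return paper_fixture("eq127")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_networks(count, seed0=0, **overrides):
    """Small random valid networks for property tests."""
    defaults = dict(nE=3, nI=3, q_zero=1)
    defaults.update(overrides)
    return [generate_network(GeneratorSpec(seed=seed0 + k, **defaults))
            for k in range(count)]
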