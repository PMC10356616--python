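import numpy as np
import pytest

from plantfish import synth_data as sd


@pytest.fixture(scope="session")
def small_experiment():
    """A compact 2-round, 8-gene experiment shared by module tests."""
    return sd.simulate_experiment(n_cells=40, n_genes=8, shape=(48, 80, 80), seed=1)


@pytest.fixture(scope="session")
def small_tissue():
    return sd.generate_tissue(30, shape=(40, 64, 64), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
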