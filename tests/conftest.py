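import numpy as np
import pytest

import msabias as mb


@pytest.fixture(scope="session")
def gtr():
    return mb.study_gtr_model()


@pytest.fixture(scope="session")
def wag():
    return mb.build_empirical_aa("WAG")


@pytest.fixture(scope="session")
def gamma4():
    return mb.discretize_gamma(mb.STUDY_GAMMA_SHAPE, 4)


@pytest.fixture(scope="session")
def gamma1():
    return mb.discretize_gamma(1.8, 1)


@pytest.fixture(scope="session")
def jc():
    """Jukes–Cantor: all exchangeabilities equal, uniform frequencies."""
    return mb.build_gtr(np.ones(6), np.full(4, 0.25))


@pytest.fixture(scope="session")
def small_sim(gtr, gamma4):
    """One small nucleotide simulation with indels on the balanced tree."""
    tree = mb.make_balanced_tree(2.0)
    return mb.simulate(
        tree, gtr, gamma4, mb.default_indel_params(4), 150, seed=42
    )
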