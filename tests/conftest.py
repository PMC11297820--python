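import numpy as np
import pytest

from stylotrace import simulate as sim
from stylotrace import trees as T
from stylotrace.characters import BINARY_STATES, CharacterMatrix


@pytest.fixture
def three_tip_tree():
    return T.tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_chars():
    return CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": "s1"})


@pytest.fixture(scope="session")
def bd_tree_10():
    return sim.simulate_bd_tree(10, birth=1.0, death=0.2, seed=42)


@pytest.fixture(scope="session")
def study_fixture():
    return sim.make_study_fixture(seed=7, n_posterior=20)


def random_binary_tree(n_tips, seed, death=0.0):
    return sim.simulate_bd_tree(n_tips, birth=1.0, death=death, seed=seed)
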