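import numpy as np
import pandas as pd
import pytest

from nucleotype.pathanalysis import CausalModel
from nucleotype.phylo import read_newick
from nucleotype.simulate import sim_tree


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1):0;")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def tree50():
    return sim_tree(50, seed=42)


@pytest.fixture
def tree100():
    return sim_tree(100, seed=11)


@pytest.fixture
def empty_dag():
    return CausalModel("empty", edges=())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
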