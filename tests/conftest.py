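import numpy as np
import pytest

from cooccurevo.orthology import OrthologyParams
from cooccurevo.traits import TraitMatrix
from cooccurevo.trees import read_newick


@pytest.fixture(scope="session")
def ortho_params():
    return OrthologyParams()


@pytest.fixture
def two_tip_tree():
    return read_newick("(A:0.8,B:1.4);")


@pytest.fixture
def five_tip_tree():
    return read_newick("(((A:0.2,B:0.4):0.1,C:0.3):0.2,(D:0.5,E:0.1):0.3);")


@pytest.fixture
def five_tip_traits():
    return TraitMatrix({"A": (1, 0), "B": (0, 0), "C": (1, 1),
                        "D": (0, 1), "E": (0, 0)})


def random_dependent_Q(rng):
    from cooccurevo.pagel import RateParamsDependent, rate_matrix
    return rate_matrix(RateParamsDependent(*rng.exponential(1.0, 8)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
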