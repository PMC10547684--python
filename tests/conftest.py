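import numpy as np
import pytest

from phylossb.simulate import make_fixture_dataset, simulate_tree
from phylossb.trees import Phylogeny


@pytest.fixture
def cherry_pair_tree():
    """((A,B),(C,D)) with unit branches."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def three_tip_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule300():
    return simulate_tree(300, "yule", scale_root_age=100.0, seed=42)


@pytest.fixture(scope="session")
def yule200():
    return simulate_tree(200, "yule", scale_root_age=100.0, seed=43)


@pytest.fixture(scope="session")
def yule50():
    return simulate_tree(50, "yule", scale_root_age=100.0, seed=44)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Medium synthetic dataset reused by table / pipeline tests."""
    return make_fixture_dataset(n_species=300, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
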