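import numpy as np
import pytest

from ssdscreen import simulate
from ssdscreen.trees import parse_newick


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — the textbook 3-taxon Brownian covariance example."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_8():
    """8-tip star tree with unit branches: Brownian covariance = identity."""
    tips = ",".join(f"sp{i}:1" for i in range(1, 9))
    return parse_newick(f"({tips});")


@pytest.fixture
def yule_tree_20():
    return simulate.simulate_tree(20, seed=11)


@pytest.fixture
def traits_20(yule_tree_20):
    return simulate.simulate_traits(yule_tree_20, seed=12, include_brain=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
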