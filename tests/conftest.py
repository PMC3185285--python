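import numpy as np
import pandas as pd
import pytest

from tephylo.datasets import study_tree
from tephylo.phylo import parse_newick


@pytest.fixture(scope="session")
def drosophila_tree():
    """The 12-species study phylogeny (root trifurcation)."""
    return study_tree()


@pytest.fixture()
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def star_tree():
    return parse_newick("(A:1,B:1,C:1);")


@pytest.fixture()
def four_tip_tree():
    # non-ultrametric, binary
    return parse_newick("((A:1.0,B:2.0):0.5,(C:0.7,D:1.5):1.2);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20110914)
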