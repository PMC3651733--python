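import numpy as np
import pytest

from modelswitch.likelihood import Alignment, PhyloTree
from modelswitch.models import ContextModelParams, GTRParams, RootMarkovChain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_taxon_tree():
    return PhyloTree.from_newick("((A:0.3,B:0.2):0.1,C:0.4);")


@pytest.fixture
def laurasiatheria_tree():
    return PhyloTree.from_newick(
        "((((cow:0.1,sheep:0.1):0.1,muntjak:0.1):0.1,pig:0.1):0.1,horse:0.1);"
    )


@pytest.fixture
def gtr_params():
    return GTRParams(
        np.array([1.0, 2.0, 0.5, 1.5, 3.0]), np.array([0.3, 0.2, 0.2, 0.3])
    )


@pytest.fixture
def context_params(rng):
    return ContextModelParams.random_from_prior(rng)


@pytest.fixture
def symmetric_context_params(rng):
    return ContextModelParams.random_from_prior(rng, strand_symmetric=True)


@pytest.fixture
def tiny_alignment():
    return Alignment.from_sequences({"A": "AC", "B": "AG", "C": "-T"})


@pytest.fixture
def uniform_chain():
    return RootMarkovChain.uniform(0)
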