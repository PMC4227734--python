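import numpy as np
import pytest

from codonscan.models import matrices
from codonscan.models.likelihood import SiteClassModel
from codonscan.trees import PhyloTree
from codonscan import simulate


@pytest.fixture(scope="session")
def equal_params() -> matrices.CodonModelParams:
    return matrices.CodonModelParams.equal(2.0)


@pytest.fixture(scope="session")
def default_tree() -> PhyloTree:
    return PhyloTree.default()


@pytest.fixture(scope="session")
def pair_tree() -> PhyloTree:
    return PhyloTree.from_newick("(a:0.5,b:0.0);")


@pytest.fixture(scope="session")
def quartet_tree() -> PhyloTree:
    return PhyloTree.from_newick("((a:0.2,b:0.3):0.15,c:0.4,d:0.25);")


def one_class_model(params, omega):
    return SiteClassModel(params, [(1.0, omega, omega)])


@pytest.fixture(scope="session")
def small_alignment(default_tree, equal_params):
    model = one_class_model(equal_params, 0.4)
    return simulate.simulate_codon_alignment(default_tree, model, 120, seed=11, gene_id="small")
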