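import numpy as np
import pytest

from alignerr import sim
from alignerr.phylo import tree_from_newick

TREE3_NEWICK = "((A:0.1,B:0.2):0.1,C:0.3);"
TREE4_NEWICK = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.15):0.1);"
# cherry-rich 8-leaf tree used for error-injection fixtures
TREE8_NEWICK = (
    "(((A:0.5,B:0.5):0.13,(C:0.5,D:0.5):0.13):0.1,"
    "((E:0.5,F:0.5):0.13,(G:0.5,H:0.5):0.13):0.1);"
)


@pytest.fixture(scope="session")
def tree3():
    return tree_from_newick(TREE3_NEWICK)


@pytest.fixture(scope="session")
def tree4():
    return tree_from_newick(TREE4_NEWICK)


@pytest.fixture(scope="session")
def tree8():
    return tree_from_newick(TREE8_NEWICK)


@pytest.fixture(scope="session")
def sim8_pool(tree8):
    """A handful of reusable simulated true MSAs on the 8-leaf tree."""
    ss = np.random.SeedSequence(20240817)
    return [
        sim.simulate_true_msa(tree8, root_length=600, seed=s)
        for s in ss.spawn(6)
    ]
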