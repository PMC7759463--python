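import logging

import numpy as np
import pytest

from phylocons.phylo_core import PhyloTree, SubstitutionModel

logging.getLogger("phylocons").setLevel(logging.ERROR)


@pytest.fixture
def jc():
    return SubstitutionModel.jukes_cantor()


@pytest.fixture
def gtr():
    return SubstitutionModel((0.3, 0.2, 0.2, 0.3), (1.0, 4.0, 1.0, 1.0, 4.0, 1.0))


@pytest.fixture
def four_leaf_tree():
    return PhyloTree.from_newick(
        "((A:0.1,B:0.2)n1:0.3,(C:0.15,D:0.25)n2:0.05)root;")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_tree(n_leaves, rng, min_bl=0.02, max_bl=0.6):
    """Random topology with uniform branch lengths, labeled A, B, C, ..."""
    from phylocons.synthetic_data import simulate_tree
    t = simulate_tree(n_leaves, 1.0, rng)
    lengths = rng.uniform(min_bl, max_bl, size=t.n_nodes)
    lengths[t.root] = 0.0
    return PhyloTree(t.labels, t.parent, lengths)
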