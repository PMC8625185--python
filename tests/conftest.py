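import numpy as np
import pytest

import ppl


@pytest.fixture
def quartet_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — balanced, ultrametric."""
    return ppl.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_tree():
    return ppl.read_newick("(((A:1,B:2):1,C:3):1,D:4);")


def random_additive_dm(n_taxa, seed):
    """Cophenetic matrix of a random tree — additive by construction."""
    tree = ppl.simulate_yule_tree(n_taxa, seed=seed, scale_height=None)
    return ppl.cophenetic_distances(tree)


@pytest.fixture
def rng():
    return np.random.default_rng(20211026)
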