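import numpy as np
import pytest

from paleotroph import synthetic_data
from paleotroph.phylo import bm_covariance, read_newick


@pytest.fixture
def balanced_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree_8():
    return read_newick("(" + ",".join(f"t{i}:1" for i in range(8)) + ");")


@pytest.fixture
def random_tree_32():
    return synthetic_data.random_coalescent_tree(32, seed=321)


@pytest.fixture
def random_tree_32_cov(random_tree_32):
    return bm_covariance(random_tree_32)


def random_trees(n_trees, max_tips, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        n = int(rng.integers(4, max_tips + 1))
        yield synthetic_data.random_coalescent_tree(n, seed=rng)
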