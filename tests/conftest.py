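import dendropy
import numpy as np
import pytest

from geneout.simulate import simulate_yule_species_tree


@pytest.fixture
def quartet():
    """The unrooted quartet AB|CD with pendants 1,2,3,4 and internal 0.5."""
    return dendropy.Tree.get(data="(a:1,b:2,(c:3,d:4):0.5);", schema="newick")


@pytest.fixture
def rng():
    return np.random.default_rng(20120821)


def random_trees(count, seed, n_min=4, n_max=20):
    """Random leaf-labeled trees with heterogeneous branch lengths (Yule
    shapes at random depths)."""
    r = np.random.default_rng(seed)
    out = []
    for _ in range(count):
        n = int(r.integers(n_min, n_max + 1))
        depth = float(r.uniform(0.5, 20.0))
        out.append(simulate_yule_species_tree(n, depth, r, ne=1.0).tree)
    return out
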