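import numpy as np
import pytest

from wgdkit.maps import make_ladder_tree
from wgdkit.simulate import make_base_genome


@pytest.fixture(scope="session")
def ladder6():
    """Five ingroup taxa plus one outgroup, ultrametric caterpillar (My)."""
    tree, spec = make_ladder_tree(
        ["t1", "t2", "t3", "t4", "t5"], ["og"], [60, 80, 100, 120, 150]
    )
    return tree, spec


@pytest.fixture(scope="session")
def base_genome():
    """Single-copy ancestral gene order: 2 chromosomes x 500 genes."""
    return make_base_genome(2, 500)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
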