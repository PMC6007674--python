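import os
import sys

import numpy as np
import pytest

# make the verification battery (scripts/acceptance.py) importable
sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "scripts"))

from phylodyn.coalescent import ConstantPopulation
from phylodyn.simulate import simulate_coalescent_tree
from phylodyn.treeio import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); contemporaneous, root height 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def serial_tree():
    """((A:0.5,B:1.5):1,C:2); tips at heights A=1, B=0, C=0.5."""
    return parse_newick("((A:0.5,B:1.5):1,C:2);")


@pytest.fixture
def random_tree():
    def make(n, seed=0, serial=False, ne=2.0):
        r = np.random.default_rng(seed)
        h = r.uniform(0.0, 2.0, n) if serial else None
        if h is not None:
            h -= h.min()
        return simulate_coalescent_tree(n, ConstantPopulation(ne), h, seed=r)

    return make
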