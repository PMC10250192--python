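import numpy as np
import pytest

import lepimacro as lm


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — root age 2, cherry age 1."""
    return lm.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_tip_tree():
    """((A:2,B:2):8,(C:5,D:5):5); — one uniquely closest pair (A,B)."""
    return lm.read_newick("((A:2,B:2):8,(C:5,D:5):5);")


@pytest.fixture
def rng():
    return lm.make_rng(20240)
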