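import numpy as np
import pytest

import klebkit as kk


@pytest.fixture
def four_leaf_tree():
    """((A:1,B:1):1,(C:1,D:1):1); — the canonical balanced quartet."""
    return kk.tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
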