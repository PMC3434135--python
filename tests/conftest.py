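import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fertevol import read_newick, reference_tree


@pytest.fixture(scope="session")
def ref_tree():
    return reference_tree()


@pytest.fixture()
def three_leaf_tree():
    return read_newick("((A:10,B:10):5,C:15);")


@pytest.fixture()
def six_leaf_tree():
    return read_newick(
        "(((A:2,B:3):1.5,(C:1,D:4):2):1,(E:3.5,F:2.5):2.5);"
    )
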