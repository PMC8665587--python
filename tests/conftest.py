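import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dupdiverge.io_models import read_newick


@pytest.fixture(scope="session")
def species_tree_3():
    return read_newick(data="((A,B),C);", species_leaves=True)


@pytest.fixture(scope="session")
def species_tree_5():
    return read_newick(data="((((A,B),C),D),E);", species_leaves=True)
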