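import numpy as np
import pytest

from gadock.fixtures import make_chain_ligand, make_toy_complex
from gadock.genome import docking_space


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def chain4():
    """4-atom chain with one rotatable bond (2-3), moving set {3, 4}."""
    return make_chain_ligand(1)


@pytest.fixture
def chain4_space(chain4):
    return docking_space(chain4, translation_halfwidth=5.0)


@pytest.fixture(scope="session")
def toy_complex_small():
    """Shared 3-torsion toy redocking problem (session-scoped: maps are big)."""
    return make_toy_complex(3, seed=42)
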