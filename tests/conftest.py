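import numpy as np
import pytest

from ptmforge.fixtures import make_toy_protein


@pytest.fixture(scope="session")
def tripeptide():
    """CYS-ALA-SER extended tripeptide used across editing tests."""
    return make_toy_protein(3, ["CYS", "ALA", "SER"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
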