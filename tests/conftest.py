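import numpy as np
import pytest

from dmfconn.dmf import DMFParameters, StructuralConnectome
from dmfconn.synthetic import make_connectome


@pytest.fixture(scope="session")
def params():
    return DMFParameters()


@pytest.fixture(scope="session")
def connectome20():
    """Session-wide 20-region synthetic connectome (density 0.3)."""
    return make_connectome(20, 0.3, 1)


@pytest.fixture(scope="session")
def single_node():
    """Two fully disconnected regions: each behaves as an isolated node."""
    return StructuralConnectome(labels=["a", "b"], C=np.zeros((2, 2)))
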