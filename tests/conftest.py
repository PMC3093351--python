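import numpy as np
import pytest

from spiketd.circuit import ArchitectureSpec, CircuitParams
from spiketd.mapping import build_mapping


@pytest.fixture(scope="session")
def spec2():
    return ArchitectureSpec(n_states=2)


@pytest.fixture(scope="session")
def spec25():
    return ArchitectureSpec(n_states=25)


@pytest.fixture(scope="session")
def circuit_params():
    return CircuitParams()


@pytest.fixture(scope="session")
def mapping2(spec2, circuit_params):
    """Mapping constants + central linearisation for the two-state circuit."""
    return build_mapping(spec2, circuit_params, dw_range=(-40.0, 40.0))
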