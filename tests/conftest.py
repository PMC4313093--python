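import numpy as np
import pytest

from quadgait.body_mechanics import MechParams
from quadgait.cpg_network import CpgParams


@pytest.fixture
def mech_params() -> MechParams:
    return MechParams()


@pytest.fixture
def cpg_params() -> CpgParams:
    return CpgParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
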