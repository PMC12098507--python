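import numpy as np
import pytest

from glekinetics import DoubleWellPotential, MemoryKernel


@pytest.fixture
def asym_potential():
    return DoubleWellPotential(u_left=3.0, u_right=5.0, l_left=1.0, l_right=0.5)


@pytest.fixture
def sym_potential():
    return DoubleWellPotential(u_left=3.0, u_right=3.0, l_left=1.0, l_right=1.0)


@pytest.fixture
def exp_kernel():
    return MemoryKernel.exponential(gamma=1.0, tau=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
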