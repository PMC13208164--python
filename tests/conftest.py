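import numpy as np
import pytest

from cyanoshade import synthetic


@pytest.fixture(scope="session")
def grid():
    return synthetic.default_wavelength_grid()


@pytest.fixture(scope="session")
def ferro(grid):
    return synthetic.ferrocyanide_curve(grid)


@pytest.fixture(scope="session")
def nitro(grid):
    return synthetic.nitroprusside_curve(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)
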