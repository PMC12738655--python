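import numpy as np
import pytest

from alphacell import CellModel, load_alpha_stopping_table, load_default_library


@pytest.fixture(scope="session")
def cell():
    return CellModel()


@pytest.fixture(scope="session")
def stopping_table():
    return load_alpha_stopping_table()


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def euler_residual(e0, path_um, table, n_steps=4000):
    """Independent fine-step Euler integration of dE/dx along a path."""
    e = float(e0)
    dx = path_um / n_steps
    for _ in range(n_steps):
        if e <= table.e_min:
            return 0.0
        e -= float(table.stopping_power(e)) * dx
    return max(e, 0.0)
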