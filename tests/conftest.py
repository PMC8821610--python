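import numpy as np
import pytest

from polscat import (assign_polarizabilities, carbon_cube, carbon_line,
                     compute_polarizability)


@pytest.fixture(scope="session")
def cube_result():
    """Polarizability of the 8-carbon, 2 A cube (shared across tests)."""
    return compute_polarizability(assign_polarizabilities(carbon_cube(2.0)))


@pytest.fixture(scope="session")
def line_result():
    """Polarizability of the 8-carbon, 2 A line along z."""
    return compute_polarizability(assign_polarizabilities(carbon_line(8, 2.0)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
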