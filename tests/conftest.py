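import math

import numpy as np
import pytest

from gixref.optics import Beam, Slab, SlabStack
from gixref.synthetic import table_stacks


@pytest.fixture(scope="session")
def beam8() -> Beam:
    return Beam(energy=8.0)


@pytest.fixture(scope="session")
def water_interface() -> SlabStack:
    """Bare air/water interface, absorption-free."""
    return SlabStack(
        slabs=(), subphase=Slab(thickness=math.inf, rho=0.334, sigma=0.0)
    )


@pytest.fixture(scope="session")
def lps_stack() -> SlabStack:
    """Intact LPS Ra monolayer on the Ca2+-free (KCl) subphase."""
    return table_stacks()["ca_free"]


@pytest.fixture(scope="session")
def q_grid() -> np.ndarray:
    return np.linspace(0.02, 0.6, 120)
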