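import numpy as np
import pytest

from adrenosim import default_parameters
from adrenosim.moa import BaselineModel
from adrenosim.parameters import (
    CellGeometry,
    KineticParameterSet,
    PARAM_NAMES,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_model():
    """Shared calibrated baseline context (compiles the solver once)."""
    return BaselineModel()


def make_zero_rate_params(**overrides) -> KineticParameterSet:
    """All rate constants and Vmax zero (Km kept positive), no cell growth.

    A convenient degenerate model: the state is frozen unless an override
    switches a specific pathway leg back on.
    """
    values = {}
    for name in PARAM_NAMES:
        values[name] = 1.0 if name.startswith("Km") else 0.0
    values.update(overrides)
    geometry = CellGeometry(cell_growth_rate=0.0,
                            cell_volume_growth_rate=0.0)
    return KineticParameterSet(values, geometry=geometry)


@pytest.fixture()
def zero_params():
    return make_zero_rate_params()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160217)
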