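import pytest

from heelfit import generate_curve, strain_grid
from heelfit.synthetic import (
    LIGAMENT_EPS_MAX,
    LIGAMENT_PIECEWISE,
    TENDON_COMBINED,
    TENDON_EPS_MAX,
    TENDON_PIECEWISE,
)


@pytest.fixture(scope="session")
def tendon_curve():
    """Noiseless 200-point piecewise curve from the bovine-tendon parameters."""
    grid = strain_grid(TENDON_EPS_MAX, 200)
    return generate_curve("piecewise", TENDON_PIECEWISE, grid)


@pytest.fixture(scope="session")
def ligament_curve():
    """Noiseless 200-point piecewise curve from the rabbit-ligament parameters."""
    grid = strain_grid(LIGAMENT_EPS_MAX, 200)
    return generate_curve("piecewise", LIGAMENT_PIECEWISE, grid)


@pytest.fixture(scope="session")
def tendon_combined_curve():
    """Noiseless 200-point combined-model curve from the tendon combined-row parameters."""
    grid = strain_grid(TENDON_EPS_MAX, 200)
    return generate_curve("combined", TENDON_COMBINED, grid)
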