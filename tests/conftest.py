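import numpy as np
import pytest

from pvatm import cewl_presets, sucrose_preset


@pytest.fixture(scope="session")
def sucrose_farfield_geometry():
    """Sucrose sample oriented with the crystal a axis along the 0-degree
    reference polarization (the far-field measurement geometry)."""
    return sucrose_preset(beta_deg=0.0)


@pytest.fixture(scope="session")
def sucrose_omega_grid():
    """30-90 cm^-1 at 0.1 cm^-1: brackets all six sucrose phonons."""
    return np.round(np.arange(300, 901) * 0.1, 10)


@pytest.fixture(scope="session")
def theta_grid_15():
    return np.arange(0.0, 361.0, 15.0)


@pytest.fixture(scope="session")
def lysozyme_fingerprints():
    return cewl_presets(crystal=1)
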