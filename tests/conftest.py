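import numpy as np
import pytest

from chromodyn import polymer
from chromodyn.fcs import FocusModel


@pytest.fixture(scope="session")
def env():
    return polymer.PhysicalEnvironment()


@pytest.fixture(scope="session")
def focus():
    return FocusModel(w_0=200.0, z_0=1000.0)


@pytest.fixture(scope="session")
def theta_spectrum_eu(env):
    """Euchromatin reference spectrum: theta rosette, R_g = 297 nm."""
    return polymer.mode_spectrum(297.0, "theta_rosette", env)


@pytest.fixture(scope="session")
def small_rosette_config():
    """A compact five-loop rosette flanked by linkers (fast to simulate)."""
    return (
        "lin(50) - dom(750)[loop(150) - loop(150) - loop(150) - loop(150) - loop(150)]"
        " - lin(50)"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160101)


@pytest.fixture(scope="session")
def rosette_map_with_truth():
    """Noise-free contact map of the ten-loop rosette with planted truth."""
    from chromodyn.domains import ROSETTE_1300_CONFIG
    from chromodyn.synthetic import simulate_contact_map

    return simulate_contact_map(ROSETTE_1300_CONFIG, n_conformations=80, seed=5)


@pytest.fixture(scope="session")
def small_rosette_ensemble(small_rosette_config):
    from chromodyn.lattice import sample_ensemble

    return sample_ensemble(small_rosette_config, 30, seed=3)
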