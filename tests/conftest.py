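import numpy as np
import pytest

from emrestore.core import DegradationModel, degrade
from emrestore.phantom import PhantomSpec, make_filaments, make_membranes, make_sarcomere


@pytest.fixture(scope="session")
def membrane_phantom():
    """Clean 256^2 membrane phantom with its binary mask."""
    vol, mask = make_membranes(PhantomSpec(kind="membranes", shape=(256, 256), seed=3))
    return vol, mask


@pytest.fixture(scope="session")
def noisy_membranes(membrane_phantom):
    """The membrane phantom degraded with sigma_noise = 0.1."""
    vol, _ = membrane_phantom
    return degrade(vol, DegradationModel(0.0, 0.1, seed=7))


@pytest.fixture(scope="session")
def sarcomere_phantom():
    vol, mask = make_sarcomere(PhantomSpec(kind="sarcomere", shape=(128, 128), seed=1))
    return vol, mask


@pytest.fixture(scope="session")
def filament_phantom():
    vol, mask, count = make_filaments(
        PhantomSpec(kind="filaments", shape=(160, 160), seed=2, n_filaments=12, radius=6)
    )
    return vol, mask, count


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
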