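import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def water_monomer():
    """Water geometry (Å), harmonic frequencies (cm^-1), sigma=2."""
    symbols = ["O", "H", "H"]
    coords = np.array([
        [0.0, 0.0, 0.1173],
        [0.0, 0.7572, -0.4692],
        [0.0, -0.7572, -0.4692],
    ])
    freqs = np.array([1595.0, 3657.0, 3756.0])
    return symbols, coords, freqs


@pytest.fixture
def nitrogen_diatomic():
    """N2 at its equilibrium bond length, sigma=2."""
    symbols = ["N", "N"]
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0977]])
    freqs = np.array([2358.6])
    return symbols, coords, freqs
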