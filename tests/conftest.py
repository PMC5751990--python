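import numpy as np
import pytest

from qusrm.acquisition import AcquisitionConfig, PhantomSpec, REFERENCE_PHANTOM
from qusrm.simulate import simulate_phantom_rf


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_phantom() -> PhantomSpec:
    """Compact diffuse phantom keeping simulations fast."""
    return PhantomSpec(extent=(8e-3, 4e-3), number_density=150.0)


@pytest.fixture(scope="session")
def small_reference() -> PhantomSpec:
    return PhantomSpec(
        effective_radius=REFERENCE_PHANTOM.effective_radius,
        number_density=150.0,
        attenuation_slope=REFERENCE_PHANTOM.attenuation_slope,
        sound_speed=REFERENCE_PHANTOM.sound_speed,
        extent=(8e-3, 4e-3),
    )


@pytest.fixture(scope="session")
def small_frame(acq, small_phantom):
    return simulate_phantom_rf(small_phantom, acq, seed=42)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
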