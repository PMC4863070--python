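import pytest
from hypothesis import HealthCheck, settings

from vo2overlap import DeviceCalibration, default_registry

settings.register_profile(
    "vo2overlap",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vo2overlap")


@pytest.fixture(scope="session")
def registry():
    """Shipped default calibrations (ParvoMedics + Douglas bag)."""
    return default_registry()


@pytest.fixture
def linear_cal():
    """Simple linear calibration for arithmetic-level checks."""
    return DeviceCalibration(
        device_id="toy_linear",
        coefficients=(0.05, 0.01),
        order=1,
        valid_range=(0.5, 5.0),
    )


@pytest.fixture
def flat_cal():
    """Constant-sigma calibration (order 1, zero slope)."""
    return DeviceCalibration(
        device_id="toy_flat",
        coefficients=(0.1, 0.0),
        order=1,
        valid_range=(0.5, 5.0),
    )
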