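import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from enthalpics.bomb import CalibrationResult
from enthalpics.quantities import Quantity


@pytest.fixture
def exact_calibration():
    """A noise-free energy equivalent, J·K⁻¹."""
    return CalibrationResult(
        eps_cal=Quantity(15907.1, 0.0, "J·K⁻¹"),
        n_runs=6,
        certificate=Quantity(-26434.0, 3.0, "J·g⁻¹"),
    )
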