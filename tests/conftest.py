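import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peptrack import DEFAULT_GEOMETRY, ScannerGeometry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def quad_geom() -> ScannerGeometry:
    """Tiny 4-crystal-per-ring geometry for hand-checkable arithmetic."""
    return ScannerGeometry(
        radius_mm=100.0,
        n_transaxial=4,
        n_rings=3,
        axial_pitch_mm=1.0,
        axial_origin_mm=0.0,
    )


@pytest.fixture
def default_geom() -> ScannerGeometry:
    return DEFAULT_GEOMETRY


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240119)
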