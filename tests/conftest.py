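import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanoclust import RadiusGrid, StudyRegion

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def region() -> StudyRegion:
    """The canonical 1 um^2 (1000 x 1000 nm) membrane-sheet window."""
    return StudyRegion.from_size(1000.0)


@pytest.fixture(scope="session")
def grid() -> RadiusGrid:
    """Default 1..240 nm radius grid with 1-nm increments."""
    return RadiusGrid()


@pytest.fixture(scope="session")
def coarse_grid() -> RadiusGrid:
    """Sparse grid for brute-force oracle comparisons."""
    return RadiusGrid(np.array([5.0, 15.0, 30.0, 60.0, 120.0, 240.0]))
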