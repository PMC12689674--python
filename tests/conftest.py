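import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.transform import Rotation

from osteoguide import FibulaParams, build_segments, make_plan

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Moderate-resolution fibula parameters shared across the suite."""
    return FibulaParams(axial_resolution=24, circumferential_resolution=36)


@pytest.fixture(scope="session")
def plan(params):
    return make_plan(params)


@pytest.fixture(scope="session")
def planned_pairs(plan):
    return [(sp.proximal_plane, sp.distal_plane) for sp in plan]


@pytest.fixture(scope="session")
def planned_segments(params, planned_pairs):
    return build_segments(params, planned_pairs)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
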