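import numpy as np
import pytest

from beevision.eye_geometry import GeometryConfig, local_facet_properties
from beevision.synthetic_data import CapEyeSpec, generate_cap_eye


@pytest.fixture(scope="session")
def cap_spec():
    return CapEyeSpec(radius_um=1000.0, facet_spacing_um=20.0, cap_half_angle_deg=60.0)


@pytest.fixture(scope="session")
def cap_eye(cap_spec):
    """Jitter-free reference cap: R=1000 um, D=20 um, theta=60 deg."""
    eye, truth = generate_cap_eye(cap_spec)
    return eye, truth


@pytest.fixture(scope="session")
def cap_props(cap_eye):
    eye, _ = cap_eye
    return local_facet_properties(eye, GeometryConfig())


@pytest.fixture(scope="session")
def small_cap_eye():
    """Cheap cap for tests that re-run the estimators many times."""
    spec = CapEyeSpec(radius_um=500.0, facet_spacing_um=25.0, cap_half_angle_deg=45.0)
    eye, truth = generate_cap_eye(spec)
    return eye, truth


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
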