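import numpy as np
import pytest

from cartmech.material import FRPEParameters
from cartmech.mesh import build_box_mesh, build_slab_mesh


@pytest.fixture(scope="session")
def unit_cube():
    return build_box_mesh(1.0, 1.0, 1.0, 1, 1, 1)


@pytest.fixture(scope="session")
def small_slab():
    return build_slab_mesh(10.0, 10.0, 2.0, 4, 8, 3)


@pytest.fixture(scope="session")
def default_params():
    return FRPEParameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_deformation_gradient(rng, scale=0.1):
    """Random F with guaranteed positive determinant."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return F
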