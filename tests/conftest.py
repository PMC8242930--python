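import numpy as np
import pytest

from hullbsp.mesh_io import TriangleMesh, make_box, make_icosphere


@pytest.fixture
def unit_cube() -> TriangleMesh:
    """Cube on [0, 1]^3: 8 vertices, 12 triangles, volume exactly 1."""
    return make_box((1.0, 1.0, 1.0), center=(0.5, 0.5, 0.5))


@pytest.fixture
def box_211() -> TriangleMesh:
    """2 x 1 x 1 box centered at the origin."""
    return make_box((2.0, 1.0, 1.0))


@pytest.fixture
def icosphere4() -> TriangleMesh:
    return make_icosphere(1.0, subdivisions=4)


@pytest.fixture
def open_cube(unit_cube) -> TriangleMesh:
    """Cube with one face removed (not watertight)."""
    return TriangleMesh(unit_cube.vertices, unit_cube.faces[:-1])


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
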