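import numpy as np
import pytest

from longicortex.surface_io import TriangleMesh
from longicortex.synthetic_cortex import icosphere_template


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere_template(3)


@pytest.fixture(scope="session")
def fine_icosphere():
    return icosphere_template(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planar_patch():
    """A flat z=0 triangulated grid patch (open mesh, CCW seen from +z)."""
    n = 6
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float),
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + n
            faces.append([a, b, a + 1])
            faces.append([a + 1, b, b + 1])
    return TriangleMesh(verts, np.array(faces))


def random_small_mesh(rng, n_faces=20):
    """A random triangle soup (not manifold) for brute-force oracles."""
    verts = rng.normal(0, 1.0, (n_faces * 3, 3))
    faces = np.arange(n_faces * 3).reshape(n_faces, 3)
    return TriangleMesh(verts, faces)
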