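import numpy as np
import pytest
from scipy.spatial import Delaunay

from carposim.mesh import ProfileSpec, TetMesh, build_mesh, compute_geometry


def semicircle_profile(radius=1.0, n=60):
    phi = np.linspace(0, np.pi, n)
    return np.column_stack([radius * np.sin(phi), radius * np.cos(phi)])


@pytest.fixture(scope="session")
def sphere_mesh():
    spec = ProfileSpec(outer_profile=semicircle_profile(), tissue_labels=["flesh"])
    return build_mesh(spec, resolution=500)


@pytest.fixture(scope="session")
def two_tissue_mesh():
    """Sphere with a half-radius inner core, pericarp/columella style."""
    spec = ProfileSpec(
        outer_profile=semicircle_profile(2.0),
        inner_profiles=[semicircle_profile(1.0)],
        tissue_labels=["pericarp", "columella"],
    )
    return build_mesh(spec, resolution=700)


@pytest.fixture()
def single_tet_mesh():
    verts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)
    mesh = TetMesh(verts, np.array([[0, 1, 2, 3]]), np.zeros(1, np.int32), ["flesh"])
    return compute_geometry(mesh)


@pytest.fixture()
def two_tet_mesh():
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float
    )
    mesh = TetMesh(
        verts, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]), np.zeros(2, np.int32), ["flesh"]
    )
    return compute_geometry(mesh)


@pytest.fixture(scope="session")
def cube_mesh():
    """Unit cube tetrahedralized from a 4^3 grid (for uniform-sampling tests)."""
    g = np.linspace(0.0, 1.0, 4)
    pts = np.array([[x, y, z] for x in g for y in g for z in g])
    rng = np.random.default_rng(0)
    pts += rng.normal(scale=1e-4, size=pts.shape)  # break co-planarity
    tri = Delaunay(pts)
    mesh = TetMesh(
        pts, tri.simplices.copy(), np.zeros(len(tri.simplices), np.int32), ["flesh"]
    )
    return compute_geometry(mesh)
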