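import numpy as np
import pytest
from scipy.spatial import ConvexHull

from stncoalign.geometry import TriangleMesh


def hull_mesh(points: np.ndarray) -> TriangleMesh:
    """Outward-oriented triangulated convex hull of a point cloud."""
    hull = ConvexHull(points)
    faces = hull.simplices.copy()
    tri = points[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    centroid = points[hull.vertices].mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, tri.mean(axis=1) - centroid) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return TriangleMesh(points, faces)


def cube_mesh(center=(0.0, 0.0, 0.0), edge: float = 1.0) -> TriangleMesh:
    """Closed unit-style cube: 8 vertices, 12 outward-oriented triangles."""
    c = np.asarray(center, dtype=float)
    h = edge / 2.0
    corners = np.array(
        [[x, y, z] for x in (-h, h) for y in (-h, h) for z in (-h, h)]
    ) + c
    return hull_mesh(corners)


@pytest.fixture
def cube() -> TriangleMesh:
    return cube_mesh()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_convex_mesh(rng: np.random.Generator, n_points: int = 30,
                       scale: float = 1.0) -> TriangleMesh:
    return hull_mesh(rng.normal(scale=scale, size=(n_points, 3)))
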