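import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stncoalign.geometry import (
    TriangleMesh,
    distance_to_surface,
    distances_to_surface,
    mesh_centroid,
    mesh_volume,
    point_in_mesh,
    points_in_mesh,
    scale_mesh,
    validate_mesh,
)

from conftest import cube_mesh, random_convex_mesh


# ------------------------------------------------------------- oracles

def ray_parity_oracle(points, mesh, direction):
    """Inside test by counting ray-triangle crossings (Moller-Trumbore)."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    tri = mesh.triangles()
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        h = np.cross(direction, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-12
        f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
        s = p - v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, e1)
        v = f * (q @ direction)
        t = f * np.einsum("ij,ij->i", e2, q)
        hit = ok & (u >= 0) & (u <= 1) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        out[i] = hit.sum() % 2 == 1
    return out


def winding_oracle(points, mesh):
    """Independent per-triangle solid-angle accumulation (pure numpy)."""
    tri = mesh.triangles()
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        a, b, c = tri[:, 0] - p, tri[:, 1] - p, tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc
               + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", b, c) * la
               + np.einsum("ij,ij->i", a, c) * lb)
        w = 2.0 * np.arctan2(num, den)
        out[i] = abs(w.sum() / (4 * np.pi)) > 0.5
    return out


def brute_distance_oracle(p, mesh):
    """Plane projection + segment clamping, minimised over all faces."""
    def seg(p, a, b):
        d = b - a
        t = np.clip(np.dot(p - a, d) / np.dot(d, d), 0, 1)
        return np.linalg.norm(p - (a + t * d))

    best = np.inf
    for face in mesh.faces:
        a, b, c = mesh.vertices[face]
        n = np.cross(b - a, c - a)
        nn = np.dot(n, n)
        q = p - np.dot(p - a, n) / nn * n
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        v = (d11 * d20 - d01 * d21) / den
        w = (d00 * d21 - d01 * d20) / den
        if v >= 0 and w >= 0 and v + w <= 1:
            d = abs(np.dot(p - a, n)) / np.sqrt(nn)
        else:
            d = min(seg(p, a, b), seg(p, b, c), seg(p, a, c))
        best = min(best, d)
    return best


# ------------------------------------------------------------- validation

class TestValidateMesh:
    def test_closed_cube_is_watertight(self, cube):
        report = validate_mesh(cube)
        assert report.ok
        assert report.watertight and report.oriented
        assert report.n_vertices == 8 and report.n_faces == 12

    def test_open_cube_is_not_watertight(self, cube):
        open_mesh = TriangleMesh(cube.vertices, cube.faces[:-1])
        report = validate_mesh(open_mesh)
        assert not report.watertight
        assert not report.ok

    def test_out_of_range_index_reported(self, cube):
        bad = cube.faces.copy()
        bad[0, 0] = 99
        report = validate_mesh(TriangleMesh(cube.vertices, bad))
        assert not report.indices_valid
        assert any("indices" in v for v in report.violations)

    def test_degenerate_face_reported(self, cube):
        bad = cube.faces.copy()
        bad[0] = [0, 0, 1]
        report = validate_mesh(TriangleMesh(cube.vertices, bad))
        assert not report.faces_nondegenerate

    def test_flipped_face_breaks_orientation(self, cube):
        bad = cube.faces.copy()
        bad[0] = bad[0][[0, 2, 1]]
        report = validate_mesh(TriangleMesh(cube.vertices, bad))
        assert report.watertight and not report.oriented

    def test_too_small_counts(self):
        verts = np.eye(3)
        faces = np.array([[0, 1, 2]] * 4)
        report = validate_mesh(TriangleMesh(verts, faces))
        assert not report.ok


# ------------------------------------------------------------- inclusion

class TestPointInMesh:
    def test_cube_centroid_inside(self, cube):
        assert point_in_mesh([0.0, 0.0, 0.0], cube)

    def test_far_point_outside(self, cube):
        assert not point_in_mesh([10.0, 0.0, 0.0], cube)

    def test_surface_point_counts_inside(self, cube):
        assert point_in_mesh([0.5, 0.0, 0.0], cube)

    def test_non_watertight_rejected(self, cube):
        open_mesh = TriangleMesh(cube.vertices, cube.faces[:-1])
        with pytest.raises(ValueError, match="watertight"):
            point_in_mesh([0, 0, 0], open_mesh)

    def test_ray_parity_oracle_agreement(self, rng):
        mesh = random_convex_mesh(rng)
        lo, hi = mesh.bounds()
        pts = rng.uniform(lo - 0.5, hi + 0.5, size=(1000, 3))
        ours = points_in_mesh(pts, mesh)
        oracle = ray_parity_oracle(pts, mesh, direction=[0.3, 0.7, 0.2])
        assert np.array_equal(ours, oracle)

    def test_translation_invariance(self, cube, rng):
        pts = rng.uniform(-1, 1, size=(200, 3))
        t = np.array([3.7, -1.2, 0.4])
        moved = TriangleMesh(cube.vertices + t, cube.faces)
        assert np.array_equal(
            points_in_mesh(pts, cube), points_in_mesh(pts + t, moved)
        )

    def test_inward_oriented_mesh_same_answer(self, cube, rng):
        flipped = TriangleMesh(cube.vertices, cube.faces[:, [0, 2, 1]])
        assert validate_mesh(flipped).ok
        pts = rng.uniform(-1, 1, size=(100, 3))
        assert np.array_equal(points_in_mesh(pts, cube),
                              points_in_mesh(pts, flipped))


# ------------------------------------------------------------- distance

class TestDistanceToSurface:
    def test_cube_center(self, cube):
        assert distance_to_surface([0, 0, 0], cube) == pytest.approx(0.5)

    def test_cube_outside_axis(self, cube):
        assert distance_to_surface([2, 0, 0], cube) == pytest.approx(1.5)

    def test_on_surface_zero(self, cube):
        assert distance_to_surface([0.5, 0.0, 0.0], cube) == pytest.approx(0.0)

    def test_brute_force_oracle(self, rng):
        mesh = random_convex_mesh(rng)
        lo, hi = mesh.bounds()
        pts = rng.uniform(lo - 1, hi + 1, size=(200, 3))
        ours = distances_to_surface(pts, mesh)
        oracle = np.array([brute_distance_oracle(p, mesh) for p in pts])
        assert np.max(np.abs(ours - oracle)) <= 1e-9

    def test_scaling_covariance(self, rng):
        mesh = random_convex_mesh(rng)
        c = mesh_centroid(mesh)
        for alpha in (0.8, 1.1, 1.2):
            scaled = scale_mesh(mesh, alpha, c)
            pts = rng.uniform(-2, 2, size=(50, 3))
            lhs = distances_to_surface(pts, scaled)
            rhs = alpha * distances_to_surface(c + (pts - c) / alpha, mesh)
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)


# ------------------------------------------------------------- scaling

class TestScaleMesh:
    def test_identity_is_exact(self, cube):
        out = scale_mesh(cube, 1.0, [10.0, 3.0, -2.0])
        assert np.array_equal(out.vertices, cube.vertices)

    def test_cube_volume_scaling(self, cube):
        scaled = scale_mesh(cube, 1.2, mesh_centroid(cube))
        assert mesh_volume(scaled) == pytest.approx(1.728, rel=1e-12)
        lo, hi = scaled.bounds()
        np.testing.assert_allclose(hi - lo, 1.2)

    def test_nonpositive_alpha_rejected(self, cube):
        with pytest.raises(ValueError):
            scale_mesh(cube, 0.0, (0, 0, 0))
        with pytest.raises(ValueError):
            scale_mesh(cube, -1.0, (0, 0, 0))

    def test_volume_alpha_cubed(self, rng):
        mesh = random_convex_mesh(rng)
        v0 = mesh_volume(mesh)
        for alpha in rng.uniform(0.8, 1.2, size=5):
            v = mesh_volume(scale_mesh(mesh, alpha, mesh_centroid(mesh)))
            assert v == pytest.approx(alpha**3 * v0, rel=1e-9)

    @given(alpha=st.floats(0.5, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_roundtrip(self, alpha):
        mesh = cube_mesh(center=(0.3, -0.2, 0.9))
        c = np.array([0.1, 0.2, 0.3])
        back = scale_mesh(scale_mesh(mesh, alpha, c), 1.0 / alpha, c)
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-12)


# ------------------------------------------------------------- centroid

class TestMeshCentroid:
    def test_cube_at_origin(self, cube):
        np.testing.assert_allclose(mesh_centroid(cube), 0.0, atol=1e-12)

    def test_translation_equivariance(self):
        shifted = cube_mesh(center=(1.0, 2.0, 3.0))
        np.testing.assert_allclose(mesh_centroid(shifted), [1, 2, 3], atol=1e-12)

    def test_tetrahedron_closed_form(self, rng):
        from conftest import hull_mesh

        pts = rng.normal(size=(4, 3))
        tet = hull_mesh(pts)
        np.testing.assert_allclose(
            mesh_centroid(tet), pts.mean(axis=0), atol=1e-12
        )

    def test_degenerate_mesh_rejected(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        faces = np.array([[0, 1, 2], [2, 1, 0], [1, 3, 2], [2, 3, 1]])
        with pytest.raises(ValueError):
            mesh_centroid(TriangleMesh(verts, faces))


# ------------------------------------------------------------- property mix

def test_winding_oracle_bulk(rng):
    hits = 0
    for k in range(10):
        mesh = random_convex_mesh(rng, n_points=20)
        lo, hi = mesh.bounds()
        pts = rng.uniform(lo, hi, size=(1000, 3))
        ours = points_in_mesh(pts, mesh)
        oracle = winding_oracle(pts, mesh)
        assert np.array_equal(ours, oracle)
        hits += ours.sum()
    assert hits > 0  # sanity: some points were actually inside
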