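"""Watertight triangle-mesh geometry: inclusion, surface distance, scaling.

All coordinates are native-space millimetres (RAS axis order for file I/O).
Inclusion queries require a watertight, consistently oriented mesh; open
surfaces are rejected rather than silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "TriangleMesh",
    "MeshValidationReport",
    "validate_mesh",
    "point_in_mesh",
    "points_in_mesh",
    "distance_to_surface",
    "distances_to_surface",
    "scale_mesh",
    "mesh_volume",
    "mesh_centroid",
]

#: points closer than this to the surface count as inside
BOUNDARY_TOL = 1e-9

# winding numbers this close to the inside/outside decision boundary fall
# back to an explicit surface-distance check
_WINDING_AMBIGUOUS = 0.01


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh in millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (V, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (F, 3), got {f.shape}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def triangles(self) -> np.ndarray:
        """Return the (F, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box as (min, max) corners."""
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass
class MeshValidationReport:
    n_vertices: int
    n_faces: int
    indices_valid: bool
    faces_nondegenerate: bool
    watertight: bool
    oriented: bool
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_mesh(mesh: TriangleMesh) -> MeshValidationReport:
    """Check the invariants required before inclusion/distance queries.

    A mesh passes when every face index is valid, each face has three
    distinct vertices, every edge is shared by exactly two faces and the
    two incident faces traverse it in opposite directions (consistent
    orientation), and there are at least 4 vertices and 4 faces.
    """
    v, f = mesh.vertices, mesh.faces
    violations: list[str] = []

    indices_valid = bool(f.size == 0 or (f.min() >= 0 and f.max() < len(v)))
    if not indices_valid:
        violations.append("face indices out of range")

    nondegenerate = bool(
        np.all((f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2]))
    )
    if not nondegenerate:
        violations.append("face with repeated vertex index")

    if len(v) < 4:
        violations.append(f"vertex count {len(v)} < 4")
    if len(f) < 4:
        violations.append(f"face count {len(f)} < 4")

    watertight = False
    oriented = False
    if indices_valid and nondegenerate and len(f) > 0:
        # directed edges of all faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        undirected = np.sort(e, axis=1)
        _, counts = np.unique(undirected, axis=0, return_counts=True)
        watertight = bool(np.all(counts == 2))
        # consistent orientation: every *directed* edge appears exactly once
        _, dcounts = np.unique(e, axis=0, return_counts=True)
        oriented = watertight and bool(np.all(dcounts == 1))
    if not watertight:
        violations.append("mesh is not watertight (edge not shared by exactly 2 faces)")
    elif not oriented:
        violations.append("mesh is not consistently oriented")

    return MeshValidationReport(
        n_vertices=len(v),
        n_faces=len(f),
        indices_valid=indices_valid,
        faces_nondegenerate=nondegenerate,
        watertight=watertight,
        oriented=oriented,
        violations=violations,
    )


def _require_valid(mesh: TriangleMesh) -> None:
    report = validate_mesh(mesh)
    if not report.ok:
        raise ValueError(
            "mesh fails validation: " + "; ".join(report.violations)
        )


@njit(cache=True)
def _winding_kernel(points, tri):  # pragma: no cover - numba-compiled
    n = points.shape[0]
    nf = tri.shape[0]
    out = np.empty(n)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        total = 0.0
        for f in range(nf):
            ax = tri[f, 0, 0] - px
            ay = tri[f, 0, 1] - py
            az = tri[f, 0, 2] - pz
            bx = tri[f, 1, 0] - px
            by = tri[f, 1, 1] - py
            bz = tri[f, 1, 2] - pz
            cx = tri[f, 2, 0] - px
            cy = tri[f, 2, 1] - py
            cz = tri[f, 2, 2] - pz
            la = np.sqrt(ax * ax + ay * ay + az * az)
            lb = np.sqrt(bx * bx + by * by + bz * bz)
            lc = np.sqrt(cx * cx + cy * cy + cz * cz)
            # a . (b x c)
            num = (
                ax * (by * cz - bz * cy)
                + ay * (bz * cx - bx * cz)
                + az * (bx * cy - by * cx)
            )
            den = (
                la * lb * lc
                + (ax * bx + ay * by + az * bz) * lc
                + (bx * cx + by * cy + bz * cz) * la
                + (ax * cx + ay * cy + az * cz) * lb
            )
            total += 2.0 * np.arctan2(num, den)
        out[i] = total / (4.0 * np.pi)
    return out


def _winding_numbers(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Generalised winding number of each point w.r.t. the surface.

    Uses the van Oosterom & Strackee solid-angle formula summed over
    triangles, normalised by 4*pi: ~1 inside, ~0 outside a closed,
    outward-oriented surface.
    """
    return _winding_kernel(
        np.ascontiguousarray(points), np.ascontiguousarray(tri)
    )


def points_in_mesh(
    points: np.ndarray, mesh: TriangleMesh, *, validated: bool = False
) -> np.ndarray:
    """Vectorised inside test for an (N, 3) array of points.

    Points within ``BOUNDARY_TOL`` of the surface count as inside.  The
    mesh must be watertight and consistently oriented.
    """
    if not validated:
        _require_valid(mesh)
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = mesh.triangles()
    w = _winding_numbers(points, tri)
    # orientation sign: outward normals give +1 inside; inward give -1
    inside = np.abs(w) > 0.5
    ambiguous = np.abs(np.abs(w) - 0.5) <= _WINDING_AMBIGUOUS
    if np.any(ambiguous):
        d = distances_to_surface(points[ambiguous], mesh, validated=True)
        inside[ambiguous] |= d <= BOUNDARY_TOL
    return inside


def point_in_mesh(point, mesh: TriangleMesh) -> bool:
    """True iff ``point`` lies inside (or on) the closed surface."""
    return bool(points_in_mesh(np.asarray(point, dtype=np.float64)[None, :], mesh)[0])


@njit(cache=True)
def _closest_sqdist_kernel(points, tri):  # pragma: no cover - numba-compiled
    """Min squared distance from each point to any triangle.

    Closest-point-on-triangle via barycentric regions (Ericson,
    *Real-Time Collision Detection*), scalarised per (point, face) pair.
    """
    n = points.shape[0]
    nf = tri.shape[0]
    out = np.empty(n)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        best = np.inf
        for f in range(nf):
            ax, ay, az = tri[f, 0, 0], tri[f, 0, 1], tri[f, 0, 2]
            abx, aby, abz = tri[f, 1, 0] - ax, tri[f, 1, 1] - ay, tri[f, 1, 2] - az
            acx, acy, acz = tri[f, 2, 0] - ax, tri[f, 2, 1] - ay, tri[f, 2, 2] - az
            apx, apy, apz = px - ax, py - ay, pz - az
            d1 = abx * apx + aby * apy + abz * apz
            d2 = acx * apx + acy * apy + acz * apz
            if d1 <= 0.0 and d2 <= 0.0:
                v, w = 0.0, 0.0  # vertex A
            else:
                bpx = px - tri[f, 1, 0]
                bpy = py - tri[f, 1, 1]
                bpz = pz - tri[f, 1, 2]
                d3 = abx * bpx + aby * bpy + abz * bpz
                d4 = acx * bpx + acy * bpy + acz * bpz
                if d3 >= 0.0 and d4 <= d3:
                    v, w = 1.0, 0.0  # vertex B
                else:
                    cpx = px - tri[f, 2, 0]
                    cpy = py - tri[f, 2, 1]
                    cpz = pz - tri[f, 2, 2]
                    d5 = abx * cpx + aby * cpy + abz * cpz
                    d6 = acx * cpx + acy * cpy + acz * cpz
                    if d6 >= 0.0 and d5 <= d6:
                        v, w = 0.0, 1.0  # vertex C
                    else:
                        vc = d1 * d4 - d3 * d2
                        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                            v, w = d1 / (d1 - d3), 0.0  # edge AB
                        else:
                            vb = d5 * d2 - d1 * d6
                            if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                                v, w = 0.0, d2 / (d2 - d6)  # edge AC
                            else:
                                va = d3 * d6 - d5 * d4
                                if (
                                    va <= 0.0
                                    and d4 - d3 >= 0.0
                                    and d5 - d6 >= 0.0
                                ):
                                    w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                                    v = 1.0 - w  # edge BC
                                else:
                                    denom = va + vb + vc
                                    v = vb / denom  # face interior
                                    w = vc / denom
            qx = ax + v * abx + w * acx
            qy = ay + v * aby + w * acy
            qz = az + v * abz + w * acz
            dx, dy, dz = px - qx, py - qy, pz - qz
            d2q = dx * dx + dy * dy + dz * dz
            if d2q < best:
                best = d2q
        out[i] = best
    return out


def distances_to_surface(
    points: np.ndarray, mesh: TriangleMesh, *, validated: bool = False
) -> np.ndarray:
    """Unsigned minimum Euclidean distance from each point to the surface."""
    if not validated:
        _require_valid(mesh)
    if mesh.n_faces == 0:
        raise ValueError("empty mesh has no surface")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = np.ascontiguousarray(mesh.triangles())
    return np.sqrt(
        _closest_sqdist_kernel(np.ascontiguousarray(points), tri)
    )


def distance_to_surface(point, mesh: TriangleMesh) -> float:
    """Distance (mm) from a single point to the mesh surface."""
    return float(
        distances_to_surface(np.asarray(point, dtype=np.float64)[None, :], mesh)[0]
    )


def scale_mesh(mesh: TriangleMesh, alpha: float, center) -> TriangleMesh:
    """Isotropically scale the mesh by ``alpha`` about ``center``.

    ``alpha == 1`` returns the vertices bit-identically (no FP round trip),
    so identity scaling is exact.
    """
    if not alpha > 0:
        raise ValueError(f"scale factor must be positive, got {alpha}")
    if alpha == 1.0:
        return TriangleMesh(mesh.vertices.copy(), mesh.faces.copy())
    center = np.asarray(center, dtype=np.float64)
    verts = center + alpha * (mesh.vertices - center)
    return TriangleMesh(verts, mesh.faces.copy())


def _signed_tet_volumes(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.triangles()
    return np.einsum(
        "fi,fi->f", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    ) / 6.0


def mesh_volume(mesh: TriangleMesh, *, validated: bool = False) -> float:
    """Enclosed volume (mm^3) via the divergence theorem.

    Positive for outward-oriented meshes; the absolute value is returned
    so inward-oriented (but consistent) meshes give the same result.
    """
    if not validated:
        _require_valid(mesh)
    return float(abs(_signed_tet_volumes(mesh).sum()))


def mesh_centroid(mesh: TriangleMesh, *, validated: bool = False) -> np.ndarray:
    """Volume centroid of the enclosed solid (mm)."""
    if not validated:
        _require_valid(mesh)
    vols = _signed_tet_volumes(mesh)
    total = vols.sum()
    if abs(total) < 1e-12:
        raise ValueError("degenerate mesh: enclosed volume is zero")
    tri = mesh.triangles()
    # centroid of each origin-tetrahedron is the mean of its 4 vertices
    tet_centroids = tri.sum(axis=1) / 4.0
    return np.asarray((vols[:, None] * tet_centroids).sum(axis=0) / total)
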