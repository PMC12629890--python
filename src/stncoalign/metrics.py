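"""Evaluation measures: fraction of STN-labelled sites inside the mesh,
lateral (perpendicular) distance between trajectories, and Dice overlap of
voxelised meshes.

Lateral distances exclude any along-trajectory (depth) component by
construction; trajectory sampling uses the 0.5 mm recording pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TriangleMesh, points_in_mesh

__all__ = [
    "Trajectory",
    "fraction_inside",
    "fit_trajectory_line",
    "lateral_distance",
    "dice_coefficient",
    "voxelize_mesh",
    "VoxelVolume",
]

RECORDING_PITCH_MM = 0.5
DEFAULT_VOXEL_MM = 0.2


@dataclass(frozen=True)
class Trajectory:
    """Straight electrode path: anchor + t * direction, t in [depth_min, depth_max]."""

    anchor: np.ndarray  # 3-vector, mm
    direction: np.ndarray  # unit 3-vector
    depth_min: float
    depth_max: float

    def __post_init__(self):
        a = np.asarray(self.anchor, dtype=np.float64)
        d = np.asarray(self.direction, dtype=np.float64)
        if a.shape != (3,) or d.shape != (3,):
            raise ValueError("anchor and direction must be 3-vectors")
        if abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("direction must be unit length (tolerance 1e-12)")
        if not self.depth_max > self.depth_min:
            raise ValueError("degenerate depth span")
        object.__setattr__(self, "anchor", a)
        object.__setattr__(self, "direction", d)

    def point_at(self, depth: float) -> np.ndarray:
        return self.anchor + depth * self.direction

    def sample(self, pitch: float = RECORDING_PITCH_MM) -> np.ndarray:
        n = int(np.floor((self.depth_max - self.depth_min) / pitch + 1e-9))
        depths = self.depth_min + pitch * np.arange(n + 1)
        return self.anchor + depths[:, None] * self.direction


def fraction_inside(positions, labels, mesh: TriangleMesh) -> float:
    """Among sites labelled STN (1), the fraction located inside the mesh."""
    positions = np.atleast_2d(np.asarray(positions, dtype=np.float64))
    labels = np.asarray(labels)
    if positions.shape[0] != labels.shape[0]:
        raise ValueError("positions and labels differ in length")
    stn = labels == 1
    if not np.any(stn):
        raise ValueError("no STN-labelled sites")
    inside = points_in_mesh(positions[stn], mesh)
    return float(inside.mean())


def fit_trajectory_line(points) -> Trajectory:
    """Total-least-squares line through >= 2 points.

    The direction is the first principal axis of the point cloud, oriented
    from the first toward the last point; the depth span covers the input
    points' projections (depth 0 at the centroid).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need at least two 3-D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0, atol=1e-12):
        raise ValueError("all points coincide; line undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    direction = direction / np.linalg.norm(direction)
    if direction @ (pts[-1] - pts[0]) < 0:
        direction = -direction
    t = centered @ direction
    return Trajectory(
        anchor=centroid, direction=direction,
        depth_min=float(t.min()), depth_max=float(t.max()),
    )


def lateral_distance(
    traj_a: Trajectory, traj_b: Trajectory, pitch: float = RECORDING_PITCH_MM
) -> float:
    """Mean perpendicular distance from points along ``traj_a`` to the
    infinite line of ``traj_b``.

    Requires the two depth spans to overlap (distances along the depth
    direction cannot be assessed and are excluded by construction).
    """
    if traj_a.depth_max < traj_b.depth_min or traj_b.depth_max < traj_a.depth_min:
        raise ValueError("trajectory depth spans do not overlap")
    pts = traj_a.sample(pitch)
    diff = pts - traj_b.anchor
    proj = (diff @ traj_b.direction)[:, None] * traj_b.direction
    perp = diff - proj
    return float(np.linalg.norm(perp, axis=1).mean())


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass(frozen=True)
class VoxelVolume:
    """Binary occupancy grid with its world-space placement."""

    mask: np.ndarray  # (nx, ny, nz) bool
    origin: np.ndarray  # world coordinate of voxel (0,0,0) centre, mm
    voxel_size: float  # isotropic edge, mm


def voxelize_mesh(
    mesh: TriangleMesh,
    voxel_size: float = DEFAULT_VOXEL_MM,
    bounds: tuple | None = None,
) -> VoxelVolume:
    """Rasterise the mesh: a voxel is set iff its centre is inside.

    ``bounds`` is an optional (min_corner, max_corner) pair; by default the
    mesh bounding box padded by one voxel is used. Pass a common ``bounds``
    when two volumes will be compared by Dice.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if bounds is None:
        lo, hi = mesh.bounds()
        lo, hi = lo - voxel_size, hi + voxel_size
    else:
        lo = np.asarray(bounds[0], dtype=np.float64)
        hi = np.asarray(bounds[1], dtype=np.float64)
    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    axes = [lo[k] + voxel_size * (np.arange(shape[k]) + 0.5) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    mesh_lo, mesh_hi = mesh.bounds()
    coarse = np.all((centers >= mesh_lo) & (centers <= mesh_hi), axis=1)
    mask = np.zeros(len(centers), dtype=bool)
    if np.any(coarse):
        mask[coarse] = points_in_mesh(centers[coarse], mesh)
    return VoxelVolume(
        mask=mask.reshape(tuple(shape)),
        origin=lo + voxel_size / 2.0,
        voxel_size=float(voxel_size),
    )
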