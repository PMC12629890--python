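"""Synthetic scene generation: STN-like meshes, Ben-gun trajectories,
simulated MER signals and ground-truth perturbations.

Every generator is a pure function of its arguments and a seed, so scenes
are bit-reproducible. Labels are always derived from the *unperturbed*
(true) geometry while site positions are reported in perturbed (observed)
coordinates — that is the precise sense in which a scene "injects" a
recoverable shift and scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .geometry import TriangleMesh, points_in_mesh, scale_mesh, validate_mesh
from .mer_signal import MerSegment
from .metrics import Trajectory

__all__ = [
    "BenGunConfig",
    "SyntheticScene",
    "CHANNEL_NAMES",
    "icosphere",
    "generate_stn_mesh",
    "generate_bengun",
    "simulate_mer_raw",
    "make_scene",
    "make_classifier_corpus",
]

#: Ben-gun channel names: Central plus the four cross arms.
CHANNEL_NAMES = ("Central", "Anterior", "Posterior", "Medial", "Lateral")

# in-plane unit offsets of each channel (ant_axis, lat_axis) multiplied by spacing
_CHANNEL_OFFSETS = {
    "Central": (0.0, 0.0),
    "Anterior": (1.0, 0.0),
    "Posterior": (-1.0, 0.0),
    "Medial": (0.0, -1.0),
    "Lateral": (0.0, 1.0),
}


@dataclass(frozen=True)
class BenGunConfig:
    """Cross ("Ben-gun") electrode layout: up to 5 parallel channels."""

    spacing: float = 2.0  # mm between Central and each peripheral channel
    step: float = 0.5  # mm between recording depths
    depth_min: float = -10.0  # mm relative to target (negative above)
    depth_max: float = 5.0
    channels: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.depth_max <= self.depth_min:
            raise ValueError("depth span is degenerate")
        unknown = set(self.channels) - set(CHANNEL_NAMES)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if len(self.channels) > 5:
            raise ValueError("at most 5 channels")

    def depths(self) -> np.ndarray:
        n = int(round((self.depth_max - self.depth_min) / self.step))
        return self.depth_min + self.step * np.arange(n + 1)


@dataclass
class SyntheticScene:
    """Fully specified ground-truth test case for co-alignment."""

    mesh: TriangleMesh
    trajectories: dict[str, Trajectory]
    site_positions: np.ndarray  # (N, 3) observed (perturbed) coordinates
    site_labels: np.ndarray  # (N,) ground-truth membership labels (pre-noise-flip)
    site_channels: np.ndarray  # (N,) channel name per site
    site_depths: np.ndarray  # (N,) depth (mm) per site
    true_shift: np.ndarray
    true_scale: float
    scale_center: np.ndarray
    label_noise_rate: float
    seed: int
    n_flipped: int = 0
    clean_labels: np.ndarray | None = field(default=None, repr=False)


def icosphere(subdivisions: int = 3) -> TriangleMesh:
    """Unit icosphere: subdivided icosahedron with vertices on the sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        verts_list = list(verts)
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            idx = midpoint.get(key)
            if idx is None:
                m = verts_list[a] + verts_list[b]
                m = m / np.linalg.norm(m)
                verts_list.append(m)
                idx = len(verts_list) - 1
                midpoint[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=np.int64)
    return TriangleMesh(verts, faces)


def generate_stn_mesh(
    seed: int,
    semi_axes=(3.0, 5.5, 2.5),
    irregularity: float = 0.0,
    subdivisions: int = 3,
    center=(0.0, 0.0, 0.0),
) -> TriangleMesh:
    """STN-like mesh: triangulated ellipsoid with a smooth random radial bump
    field of relative amplitude ``irregularity``.

    Default semi-axes give a ~6 mm mediolateral (x) full extent. The
    perturbation is star-shaped by construction as long as it stays below
    100% relative amplitude; larger values raise an error.
    """
    semi_axes = np.asarray(semi_axes, dtype=np.float64)
    if np.any(semi_axes <= 0):
        raise ValueError("semi_axes must be positive")
    if irregularity < 0:
        raise ValueError("irregularity must be non-negative")
    if irregularity >= 1.0:
        raise ValueError(
            "irregularity >= 1 can collapse the radial field "
            "(non-star-shaped surface)"
        )
    base = icosphere(subdivisions)
    u = base.vertices  # unit directions
    radial = np.ones(len(u))
    if irregularity > 0:
        rng = np.random.default_rng(seed)
        n_bumps = 8
        dirs = rng.normal(size=(n_bumps, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coeffs = rng.normal(size=n_bumps)
        width = 0.6  # radians-ish on the unit sphere
        bumps = np.exp(-np.linalg.norm(u[:, None, :] - dirs[None], axis=2) ** 2
                       / (2 * width**2))
        pert = bumps @ coeffs
        pert = pert / max(np.abs(pert).max(), 1e-12)
        radial = 1.0 + irregularity * pert
        if np.any(radial <= 0):
            raise ValueError(
                f"irregularity {irregularity} collapses the surface "
                "(non-star-shaped / self-intersecting)"
            )
    verts = np.asarray(center) + radial[:, None] * u * semi_axes
    mesh = TriangleMesh(verts, base.faces)
    report = validate_mesh(mesh)
    if not report.ok:
        raise ValueError(f"generated mesh invalid: {report.violations}")
    return mesh


def _perpendicular_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal (anterior-ish, lateral-ish) in-plane axes."""
    d = np.asarray(direction, dtype=np.float64)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    ant = ref - (ref @ d) * d
    ant /= np.linalg.norm(ant)
    lat = np.cross(d, ant)
    return ant, lat


#: default oblique approach (lateral + anterior tilt, mostly inferior),
#: roughly matching a clinical frontal entry; unit length
DEFAULT_APPROACH = tuple(
    np.array([0.3, 0.45, -1.0]) / np.linalg.norm([0.3, 0.45, -1.0])
)


def generate_bengun(
    config: BenGunConfig,
    target=(0.0, 0.0, 0.0),
    approach_direction=DEFAULT_APPROACH,
) -> tuple[dict[str, Trajectory], dict[str, np.ndarray]]:
    """Build parallel Ben-gun trajectories and their recording positions.

    Returns ``(trajectories, positions)`` where ``positions[channel]`` is an
    (n_depths, 3) array of recording coordinates, one row per depth from
    ``config.depths()``. Depth 0 is the planned target; negative depths lie
    above (before) the target along the approach.
    """
    target = np.asarray(target, dtype=np.float64)
    d = np.asarray(approach_direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("approach_direction must be non-zero")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn("approach_direction not unit length; normalising")
    d = d / norm
    ant, lat = _perpendicular_frame(d)
    depths = config.depths()
    trajectories: dict[str, Trajectory] = {}
    positions: dict[str, np.ndarray] = {}
    for name in config.channels:
        oa, ol = _CHANNEL_OFFSETS[name]
        anchor = target + config.spacing * (oa * ant + ol * lat)
        trajectories[name] = Trajectory(
            anchor=anchor, direction=d,
            depth_min=float(depths[0]), depth_max=float(depths[-1]),
        )
        positions[name] = anchor + depths[:, None] * d
    return trajectories, positions


def _biexponential_spike(rate_hz: float, fs: float) -> np.ndarray:
    """Fixed biexponential extracellular spike template (cosmetic realism)."""
    t = np.arange(0.0, 0.003, 1.0 / fs)
    w = np.exp(-t / 3e-4) - np.exp(-t / 1e-4)
    return -w / np.abs(w).max()


def simulate_mer_raw(
    positions: dict[str, np.ndarray],
    depths: np.ndarray,
    mesh: TriangleMesh,
    inside_sigma: float = 25.0,
    outside_sigma: float = 10.0,
    duration: float = 10.0,
    rate: float = 24000.0,
    seed: int = 0,
    band=(500.0, 5000.0),
    spike_rate_hz: float = 40.0,
    spike_amplitude: float = 40.0,
) -> dict[str, list[MerSegment]]:
    """Simulate raw MER segments for every recording position.

    Gaussian background of ``outside_sigma`` uV everywhere; inside the mesh
    the variance is raised to ``inside_sigma``^2 and Poisson spike events are
    superimposed. A 4th-order zero-phase band-pass is applied, with the noise
    pre-compensated for the filter's white-noise gain so that the *filtered*
    background RMS matches the requested sigmas.
    """
    if not inside_sigma > outside_sigma > 0:
        raise ValueError("need inside_sigma > outside_sigma > 0")
    if band is not None and rate <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {rate} Hz cannot represent band up to {band[1]} Hz"
        )
    n = int(round(duration * rate))
    sos = None
    gain = 1.0
    if band is not None:
        sos = sps.butter(4, band, btype="bandpass", fs=rate, output="sos")
        # RMS gain on white noise; sosfiltfilt runs the filter twice, so the
        # effective power response is |H|^4
        _, h = sps.sosfreqz(sos, worN=4096, fs=rate)
        gain = float(np.sqrt(np.mean(np.abs(h) ** 4)))
    spike = _biexponential_spike(spike_rate_hz, rate)
    rng = np.random.default_rng(seed)
    out: dict[str, list[MerSegment]] = {}
    for name in sorted(positions):
        pos = positions[name]
        inside = points_in_mesh(pos, mesh)
        segs: list[MerSegment] = []
        for k, depth in enumerate(depths):
            sigma = inside_sigma if inside[k] else outside_sigma
            x = rng.normal(0.0, sigma / gain, size=n)
            if inside[k]:
                n_spikes = rng.poisson(spike_rate_hz * duration)
                starts = rng.integers(0, n - len(spike), size=n_spikes)
                for s0 in starts:
                    x[s0:s0 + len(spike)] += spike_amplitude * spike
            if sos is not None:
                x = sps.sosfiltfilt(sos, x)
            segs.append(
                MerSegment(samples=x, sampling_rate=rate,
                           depth=float(depth), trajectory_id=name)
            )
        out[name] = segs
    return out


def make_scene(
    seed: int,
    true_shift=(0.0, 0.0, 0.0),
    true_scale: float = 1.0,
    label_noise_rate: float = 0.0,
    bengun: BenGunConfig | None = None,
    semi_axes=(3.0, 5.5, 2.5),
    irregularity: float = 0.15,
    subdivisions: int = 2,
    target_offset=(0.0, 0.0, 0.0),
    approach_direction=DEFAULT_APPROACH,
) -> SyntheticScene:
    """Compose a complete synthetic co-alignment scene.

    The imaging mesh M is generated around the origin; the "true"
    (electrophysiological) STN is M scaled by ``true_scale`` about its
    centroid. True site positions get labels from membership in that true
    STN, then positions are perturbed by ``+true_shift`` to give the
    observed coordinates. Co-alignment of the observed scene must therefore
    recover ``(true_shift, true_scale)`` (cost 0 at the truth when
    ``label_noise_rate`` is 0).
    """
    true_shift = np.asarray(true_shift, dtype=np.float64)
    if np.linalg.norm(true_shift) > 3.0 + 1e-12:
        warnings.warn("true shift exceeds the 3 mm clinical bound")
    if not 0.8 - 1e-12 <= true_scale <= 1.2 + 1e-12:
        warnings.warn("true scale outside the [0.8, 1.2] clinical bound")
    rng = np.random.default_rng(seed)
    mesh_seed, noise_seed = rng.integers(0, 2**31 - 1, size=2)
    mesh = generate_stn_mesh(
        int(mesh_seed), semi_axes=semi_axes, irregularity=irregularity,
        subdivisions=subdivisions,
    )
    from .geometry import mesh_centroid  # local import avoids cycle at module load

    center = mesh_centroid(mesh)
    cfg = bengun if bengun is not None else BenGunConfig()
    trajectories, positions = generate_bengun(
        cfg,
        target=center + np.asarray(target_offset, dtype=np.float64),
        approach_direction=approach_direction,
    )
    true_mesh = scale_mesh(mesh, true_scale, center)

    chans, depths_all, pos_true = [], [], []
    depths = cfg.depths()
    for name in cfg.channels:
        chans += [name] * len(depths)
        depths_all += list(depths)
        pos_true.append(positions[name])
    pos_true = np.concatenate(pos_true)
    labels = points_in_mesh(pos_true, true_mesh).astype(np.int64)

    noisy = labels.copy()
    n_flipped = 0
    if label_noise_rate > 0:
        flip_rng = np.random.default_rng(int(noise_seed))
        flips = flip_rng.random(len(labels)) < label_noise_rate
        noisy[flips] = 1 - noisy[flips]
        n_flipped = int(flips.sum())

    observed = pos_true + true_shift
    # shift the trajectory geometry consistently with the site positions
    shifted_traj = {
        name: Trajectory(
            anchor=t.anchor + true_shift, direction=t.direction,
            depth_min=t.depth_min, depth_max=t.depth_max,
        )
        for name, t in trajectories.items()
    }
    return SyntheticScene(
        mesh=mesh,
        trajectories=shifted_traj,
        site_positions=observed,
        site_labels=noisy,
        site_channels=np.asarray(chans),
        site_depths=np.asarray(depths_all),
        true_shift=true_shift,
        true_scale=float(true_scale),
        scale_center=center,
        label_noise_rate=float(label_noise_rate),
        seed=int(seed),
        n_flipped=n_flipped,
        clean_labels=labels,
    )


def make_classifier_corpus(
    n_tracks: int = 200,
    n_depths: int = 31,
    inside_mu: float = 3.0,
    inside_sd: float = 0.1,
    outside_mu: float = 1.0,
    outside_sd: float = 0.1,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Separable synthetic NRMS corpus for classifier training/evaluation.

    Each track has one contiguous in-STN segment (possibly empty) with NRMS
    drawn around ``inside_mu``; background depths draw around ``outside_mu``.
    Returns a list of ``(nrms_values, labels)`` pairs.
    """
    rng = np.random.default_rng(seed)
    corpus = []
    for _ in range(n_tracks):
        labels = np.zeros(n_depths, dtype=np.int64)
        if rng.random() > 0.1:  # 10% of tracks miss the STN entirely
            length = int(rng.integers(4, max(5, n_depths // 2)))
            start = int(rng.integers(2, n_depths - length))
            labels[start:start + length] = 1
        nrms = np.where(
            labels == 1,
            rng.normal(inside_mu, inside_sd, size=n_depths),
            rng.normal(outside_mu, outside_sd, size=n_depths),
        )
        nrms = np.clip(nrms, 1e-6, None)
        corpus.append((nrms, labels))
    return corpus
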