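"""NRMS features from raw microelectrode-recording segments.

The normalised RMS at each depth is the segment RMS divided by the mean RMS
over the first ``n_baseline`` (pre-STN) depths of the same trajectory, so
background activity sits near 1 and STN activity well above it. The 500-5000
Hz band-pass is treated as an acquisition property of the input and is not
re-applied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MerSegment",
    "NrmsSequence",
    "compute_rms",
    "compute_nrms",
    "DEFAULT_N_BASELINE",
]

DEFAULT_N_BASELINE = 5


@dataclass(frozen=True)
class MerSegment:
    """One raw recording: ~10 s of signal at a single depth.

    ``depth`` is signed mm relative to the planned target (negative above).
    """

    samples: np.ndarray  # amplitude series, uV
    sampling_rate: float  # Hz (nominal 24000)
    depth: float
    trajectory_id: str

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class NrmsSequence:
    """Dimensionless NRMS value per depth for one trajectory."""

    trajectory_id: str
    depths: np.ndarray  # mm, acquisition order
    nrms: np.ndarray  # > 0, one per depth
    baseline_rms: float  # normalising constant, uV

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=np.float64)
        n = np.asarray(self.nrms, dtype=np.float64)
        if d.shape != n.shape or d.ndim != 1 or d.size == 0:
            raise ValueError("depths and nrms must be matching non-empty 1-D arrays")
        if np.any(n <= 0):
            raise ValueError("nrms values must be strictly positive")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "nrms", n)

    def __len__(self) -> int:
        return len(self.depths)


def compute_rms(segment: MerSegment) -> float:
    """Root-mean-square amplitude (uV) of one segment."""
    return float(np.sqrt(np.mean(segment.samples**2)))


def compute_nrms(
    segments: list[MerSegment],
    n_baseline: int = DEFAULT_N_BASELINE,
    baseline_labels: np.ndarray | None = None,
) -> NrmsSequence:
    """Normalise per-depth RMS by the mean RMS of the first ``n_baseline`` depths.

    ``segments`` must all belong to one trajectory and be in acquisition
    (depth) order. If ``baseline_labels`` is given (one 0/1 label per
    segment), a warning is raised when any baseline depth is labelled STN,
    since the baseline is meant to capture pre-STN background activity.
    """
    if not segments:
        raise ValueError("no segments given")
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if len(segments) < n_baseline:
        raise ValueError(
            f"need at least n_baseline={n_baseline} segments, got {len(segments)}"
        )
    traj_ids = {s.trajectory_id for s in segments}
    if len(traj_ids) != 1:
        raise ValueError(f"segments span multiple trajectories: {sorted(traj_ids)}")
    depths = np.array([s.depth for s in segments])
    if np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing in acquisition order")
    rms = np.array([compute_rms(s) for s in segments])
    baseline = float(np.mean(rms[:n_baseline]))
    if baseline <= 0:
        raise ValueError("baseline RMS is zero")
    if baseline_labels is not None and np.any(
        np.asarray(baseline_labels)[:n_baseline] == 1
    ):
        warnings.warn(
            "baseline window contains STN-labelled depths; "
            "NRMS normalisation may be biased"
        )
    return NrmsSequence(
        trajectory_id=segments[0].trajectory_id,
        depths=depths,
        nrms=rms / baseline,
        baseline_rms=baseline,
    )
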