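"""Tabular file formats tying the pipeline stages together.

Schemas (all CSV, 0-based indices, depths in signed mm with target = 0 and
negative above target):

- sites:  trajectory_id, depth_mm, x, y, z, label
- NRMS:   trajectory_id, depth_mm, nrms
- predictions: trajectory_id, depth_mm, probability, label
- raw segments: trajectory_id, depth_mm, sample_index, amplitude_uv
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coalign import RecordingSite
from .mer_classifier import DepthLabels
from .mer_signal import MerSegment, NrmsSequence

__all__ = [
    "read_sites", "write_sites",
    "read_nrms", "write_nrms",
    "read_predictions", "write_predictions",
    "read_raw_segments", "write_raw_segments",
]

_SITES_COLUMNS = ["trajectory_id", "depth_mm", "x", "y", "z", "label"]
_NRMS_COLUMNS = ["trajectory_id", "depth_mm", "nrms"]
_PRED_COLUMNS = ["trajectory_id", "depth_mm", "probability", "label"]
_RAW_COLUMNS = ["trajectory_id", "depth_mm", "sample_index", "amplitude_uv"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(repr(c) for c in missing)}"
        )


def read_sites(path) -> list[RecordingSite]:
    df = pd.read_csv(path)
    _check_columns(df, _SITES_COLUMNS, path)
    bad = df.index[~df["label"].isin((0, 1))]
    if len(bad):
        raise ValueError(f"{path}: non-binary 'label' at row {bad[0]}")
    return [
        RecordingSite(
            position=np.array([row.x, row.y, row.z]),
            label=int(row.label),
            trajectory_id=str(row.trajectory_id),
            depth=float(row.depth_mm),
        )
        for row in df.itertuples()
    ]


def write_sites(sites: list[RecordingSite], path) -> None:
    df = pd.DataFrame(
        {
            "trajectory_id": [s.trajectory_id for s in sites],
            "depth_mm": [s.depth for s in sites],
            "x": [s.position[0] for s in sites],
            "y": [s.position[1] for s in sites],
            "z": [s.position[2] for s in sites],
            "label": [s.label for s in sites],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_nrms(path) -> list[NrmsSequence]:
    """One :class:`NrmsSequence` per trajectory, depth-sorted."""
    df = pd.read_csv(path)
    _check_columns(df, _NRMS_COLUMNS, path)
    out = []
    for traj_id, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("depth_mm")
        out.append(
            NrmsSequence(
                trajectory_id=str(traj_id),
                depths=grp["depth_mm"].to_numpy(dtype=float),
                nrms=grp["nrms"].to_numpy(dtype=float),
                baseline_rms=float(grp["baseline_rms"].iloc[0])
                if "baseline_rms" in grp.columns else float("nan"),
            )
        )
    return out


def write_nrms(sequences: list[NrmsSequence], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "trajectory_id": seq.trajectory_id,
                "depth_mm": seq.depths,
                "nrms": seq.nrms,
                "baseline_rms": seq.baseline_rms,
            }
        )
        for seq in sequences
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_predictions(path) -> list[DepthLabels]:
    df = pd.read_csv(path)
    _check_columns(df, _PRED_COLUMNS, path)
    out = []
    for traj_id, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("depth_mm")
        out.append(
            DepthLabels(
                trajectory_id=str(traj_id),
                depths=grp["depth_mm"].to_numpy(dtype=float),
                labels=grp["label"].to_numpy(dtype=int),
                probabilities=grp["probability"].to_numpy(dtype=float),
            )
        )
    return out


def write_predictions(predictions: list[DepthLabels], path) -> None:
    frames = []
    for p in predictions:
        probs = p.probabilities
        if probs is None:
            probs = p.labels.astype(float)
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": p.trajectory_id,
                    "depth_mm": p.depths,
                    "probability": probs,
                    "label": p.labels,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_raw_segments(path, sampling_rate: float = 24000.0) -> dict[str, list[MerSegment]]:
    """Columnar raw-signal container -> segments grouped by trajectory."""
    df = pd.read_csv(path)
    _check_columns(df, _RAW_COLUMNS, path)
    out: dict[str, list[MerSegment]] = {}
    for (traj_id, depth), grp in df.groupby(["trajectory_id", "depth_mm"], sort=True):
        grp = grp.sort_values("sample_index")
        out.setdefault(str(traj_id), []).append(
            MerSegment(
                samples=grp["amplitude_uv"].to_numpy(dtype=float),
                sampling_rate=sampling_rate,
                depth=float(depth),
                trajectory_id=str(traj_id),
            )
        )
    for traj_id in out:
        out[traj_id].sort(key=lambda s: s.depth)
    return out


def write_raw_segments(segments: dict[str, list[MerSegment]], path) -> None:
    frames = []
    for traj_id in sorted(segments):
        for seg in segments[traj_id]:
            frames.append(
                pd.DataFrame(
                    {
                        "trajectory_id": traj_id,
                        "depth_mm": seg.depth,
                        "sample_index": np.arange(len(seg.samples)),
                        "amplitude_uv": seg.samples,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.8g"
    )
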