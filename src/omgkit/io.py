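"""File formats, core containers, configuration loading, and logging.

Two CSV formats are the on-disk interface of the pipeline:

* **pose CSV** — one row per (frame, tag):
  ``frame_id,timestamp,tag_id,x,y,z,yaw,pitch,roll,detected``
  with positions in meters and angles in radians, both expressed in the
  camera reference frame.  Rows absent for a (frame, tag) pair are read back
  as undetected samples.
* **stimulus CSV** — one row per frame:
  ``frame_id,timestamp,<dof_1>,...,<dof_D>`` with activations in [0, 1].

Floats are written with 10 significant digits so a write/read round trip is
lossless at working precision.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .config import (
    POSE_CHANNELS,
    DeformationConfig,
    GridSpec,
    PipelineConfig,
    ProtocolConfig,
)

__all__ = [
    "MarkerTrajectorySet",
    "StimulusProfile",
    "read_pose_csv",
    "write_pose_csv",
    "read_stimulus_csv",
    "write_stimulus_csv",
    "load_config",
    "logger",
]

logger = logging.getLogger("omgkit")

_FLOAT_FMT = "%.10g"
POSE_COLUMNS = ("frame_id", "timestamp", "tag_id") + POSE_CHANNELS + ("detected",)


@dataclass
class StimulusProfile:
    """Ground-truth activation profile: a T x D matrix of values in [0, 1].

    One column per degree of freedom; movements are stimulated sequentially,
    so at most one DOF is nonzero at any frame.
    """

    timestamps: np.ndarray
    values: np.ndarray
    dof_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        if self.values.shape != (self.timestamps.size, len(self.dof_names)):
            raise ValueError("timestamps / values / dof_names shapes disagree")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("stimulus values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_dofs(self) -> int:
        return self.values.shape[1]


@dataclass
class MarkerTrajectorySet:
    """Per-frame 6-DOF poses of all tracked markers.

    ``poses`` has shape (T, M, 6) with channel order (x, y, z, yaw, pitch,
    roll); ``detected`` flags which (frame, marker) samples the detector
    actually produced.  ``marker_ids`` encodes the proximal-to-distal row
    order of the physical layout: the first ids are the most proximal.
    """

    marker_ids: Tuple[int, ...]
    timestamps: np.ndarray
    poses: np.ndarray
    detected: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.poses = np.asarray(self.poses, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        T, M = self.timestamps.size, len(self.marker_ids)
        if self.poses.shape != (T, M, 6):
            raise ValueError(f"poses must have shape ({T}, {M}, 6)")
        if self.detected.shape != (T, M):
            raise ValueError(f"detected must have shape ({T}, {M})")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.poses.shape[0]

    @property
    def n_markers(self) -> int:
        return self.poses.shape[1]

    def subset(self, marker_ids: Sequence[int]) -> "MarkerTrajectorySet":
        """Restrict to the given marker ids, preserving their order."""
        if len(marker_ids) == 0:
            raise ValueError("marker subset must not be empty")
        index = {m: i for i, m in enumerate(self.marker_ids)}
        unknown = [m for m in marker_ids if m not in index]
        if unknown:
            raise ValueError(f"unknown marker ids: {unknown}")
        cols = [index[m] for m in marker_ids]
        return replace(
            self,
            marker_ids=tuple(marker_ids),
            poses=self.poses[:, cols, :].copy(),
            detected=self.detected[:, cols].copy(),
        )


# ---------------------------------------------------------------------------
# pose CSV
# ---------------------------------------------------------------------------

def write_pose_csv(path: Union[str, Path], traj: MarkerTrajectorySet) -> None:
    """Write a trajectory set in the long pose-CSV format (all samples,
    including undetected ones, which keep their stored pose values)."""
    T, M = traj.n_frames, traj.n_markers
    frame = np.repeat(np.arange(T), M)
    df = pd.DataFrame(
        {
            "frame_id": frame,
            "timestamp": np.repeat(traj.timestamps, M),
            "tag_id": np.tile(np.asarray(traj.marker_ids), T),
        }
    )
    flat = traj.poses.reshape(T * M, 6)
    for j, ch in enumerate(POSE_CHANNELS):
        df[ch] = flat[:, j]
    df["detected"] = traj.detected.reshape(T * M).astype(int)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_pose_csv(path: Union[str, Path], fps: float | None = None) -> MarkerTrajectorySet:
    """Read a pose CSV into a :class:`MarkerTrajectorySet`.

    Frames are aligned across tags on ``frame_id``; a (frame, tag) pair with
    no row becomes an undetected sample with NaN pose.  ``fps`` is inferred
    from the median timestamp step when not given.
    """
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(POSE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown pose CSV columns: {sorted(unknown)}")
    missing = set(POSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pose CSV misses columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("pose CSV contains no rows")

    dup = df.duplicated(subset=["frame_id", "tag_id"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (frame_id, tag_id) = ({int(row.frame_id)}, {int(row.tag_id)})"
        )
    for tag, grp in df.groupby("tag_id", sort=False):
        fid = grp["frame_id"].to_numpy()
        if np.any(np.diff(fid) <= 0):
            bad = int(fid[np.argmax(np.diff(fid) <= 0) + 1])
            raise ValueError(
                f"frame_id not strictly increasing for tag {int(tag)} near frame {bad}"
            )

    frame_ids = np.unique(df["frame_id"].to_numpy())
    marker_ids = tuple(int(t) for t in pd.unique(df["tag_id"]))
    frame_pos = {f: i for i, f in enumerate(frame_ids)}
    tag_pos = {m: j for j, m in enumerate(marker_ids)}
    T, M = frame_ids.size, len(marker_ids)

    poses = np.full((T, M, 6), np.nan)
    detected = np.zeros((T, M), dtype=bool)
    timestamps = np.full(T, np.nan)
    ti = df["frame_id"].map(frame_pos).to_numpy()
    tj = df["tag_id"].map(tag_pos).to_numpy()
    poses[ti, tj, :] = df[list(POSE_CHANNELS)].to_numpy()
    detected[ti, tj] = df["detected"].to_numpy().astype(bool)
    timestamps[ti] = df["timestamp"].to_numpy()

    if fps is None:
        steps = np.diff(timestamps)
        steps = steps[np.isfinite(steps) & (steps > 0)]
        fps = 1.0 / float(np.median(steps)) if steps.size else 1.0
    return MarkerTrajectorySet(
        marker_ids=marker_ids,
        timestamps=timestamps,
        poses=poses,
        detected=detected,
        fps=float(fps),
    )


# ---------------------------------------------------------------------------
# stimulus CSV
# ---------------------------------------------------------------------------

def write_stimulus_csv(path: Union[str, Path], stimulus: StimulusProfile) -> None:
    df = pd.DataFrame(
        {"frame_id": np.arange(stimulus.n_frames), "timestamp": stimulus.timestamps}
    )
    for d, name in enumerate(stimulus.dof_names):
        df[name] = stimulus.values[:, d]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_stimulus_csv(path: Union[str, Path]) -> StimulusProfile:
    """Read a stimulus CSV; values outside [0, 1] are rejected (not clipped)."""
    df = pd.read_csv(path)
    for col in ("frame_id", "timestamp"):
        if col not in df.columns:
            raise ValueError(f"stimulus CSV misses column {col!r}")
    dof_names = tuple(c for c in df.columns if c not in ("frame_id", "timestamp"))
    if not dof_names:
        raise ValueError("stimulus CSV has no DOF columns")
    values = df[list(dof_names)].to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"stimulus value out of [0, 1] at row {int(i)}, column {dof_names[j]!r}: "
            f"{values[i, j]!r}"
        )
    return StimulusProfile(
        timestamps=df["timestamp"].to_numpy(dtype=float),
        values=values,
        dof_names=dof_names,
    )


# ---------------------------------------------------------------------------
# configuration file
# ---------------------------------------------------------------------------

_PROTOCOL_KEYS = {
    "dof_names", "flexion_s", "rest_s", "repetitions", "fps", "ramp_s", "lead_in_s",
}
_DEFORMATION_KEYS = {
    "n_markers", "n_rows", "n_cols", "noise_sd", "drift_amplitude",
    "drift_period_s", "dropout_rate", "deformation_seed",
}
_PIPELINE_KEYS = {
    "low_hz", "high_hz", "filter_order", "causal", "d",
    "lambda_exponents", "lambda_points", "sigma_exponents", "sigma_points",
    "schemes", "methods", "seed", "marker_subset", "paired", "clip",
}


def load_config(
    path: Union[str, Path],
) -> Tuple[ProtocolConfig, DeformationConfig, PipelineConfig]:
    """Load a flat key-value (YAML) configuration file.

    Unspecified keys fall back to the reference defaults (15 fps, 0.01/0.5 Hz
    second-order band-pass, D = 500, 10-point log grids).  Unknown keys are
    rejected to protect against typos.  All effective values are logged.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    raw = {str(k).lower(): v for k, v in raw.items()}
    unknown = set(raw) - _PROTOCOL_KEYS - _DEFORMATION_KEYS - _PIPELINE_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    proto_kwargs = {k: raw[k] for k in _PROTOCOL_KEYS if k in raw}
    if "dof_names" in proto_kwargs:
        proto_kwargs["dof_names"] = tuple(proto_kwargs["dof_names"])
    protocol = ProtocolConfig(**proto_kwargs)

    deform_kwargs = {}
    for k in _DEFORMATION_KEYS:
        if k in raw:
            key = "seed" if k == "deformation_seed" else k
            val = raw[k]
            if k in ("noise_sd", "drift_amplitude"):
                val = tuple(np.broadcast_to(np.asarray(val, dtype=float), (6,)))
            deform_kwargs[key] = val
    deformation = DeformationConfig(**deform_kwargs)

    grid = GridSpec.from_exponents(
        lambda_exponents=tuple(raw.get("lambda_exponents", (-6.0, 0.0))),
        lambda_points=int(raw.get("lambda_points", 10)),
        sigma_exponents=tuple(raw.get("sigma_exponents", (-3.0, 3.0))),
        sigma_points=int(raw.get("sigma_points", 10)),
    )
    pipe_kwargs = {"grid": grid}
    for k in _PIPELINE_KEYS - {
        "lambda_exponents", "lambda_points", "sigma_exponents", "sigma_points",
    }:
        if k in raw:
            key = {"d": "D"}.get(k, k)
            val = raw[k]
            if k in ("schemes", "marker_subset") and val is not None:
                val = tuple(val)
            if k == "methods":
                val = tuple(str(v).lower() for v in val)
            pipe_kwargs[key] = val
    pipeline = PipelineConfig(**pipe_kwargs)

    logger.info("protocol config: %s", protocol)
    logger.info("deformation config: %s", deformation)
    logger.info("pipeline config: %s", pipeline)
    return protocol, deformation, pipeline
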