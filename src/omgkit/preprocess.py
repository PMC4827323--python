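"""Preprocessing: dropout imputation, band-pass filtering, feature building.

The raw marker poses carry a large DC offset (the static pose of the arm
under the camera), slow drift, and high-frequency tracking jitter; the
movement-related bulging lives in between.  A second-order Butterworth
band-pass (0.01–0.5 Hz) removes both ends and centers every channel around
zero.  Filtering is zero-phase by default (forward-backward): the analysis
is offline and the regression targets an unshifted stimulus, so a causal
filter would introduce an uncompensated phase lag.  A causal variant is
available for comparison.

Undetected marker samples are conservatively replaced by the marker's last
known pose before any filtering.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .io import MarkerTrajectorySet, StimulusProfile
from .config import POSE_CHANNELS

__all__ = [
    "FeatureMatrix",
    "OnOffMask",
    "impute_last_known",
    "bandpass",
    "bandpass_sos",
    "build_features",
    "onoff_mask",
]


@dataclass
class FeatureMatrix:
    """T x P matrix of filtered pose features, P = 6 * n_markers.

    Column ``6*i + j`` is pose channel ``j`` (x, y, z, yaw, pitch, roll) of
    marker ``i`` (marker-major order).  Columns are centered: after the
    band-pass each column mean is zero to within 1e-6 of its SD.
    """

    X: np.ndarray
    fps: float
    marker_ids: Tuple[int, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[1] != 6 * len(self.marker_ids):
            raise ValueError("X must have 6 columns per marker")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> Tuple[str, ...]:
        return tuple(
            f"tag{m}_{ch}" for m in self.marker_ids for ch in POSE_CHANNELS
        )


@dataclass
class OnOffMask:
    """Per-DOF labelling of plateau ("on-off") vs intermediate frames.

    ``is_plateau[t, d]`` is true when DOF ``d`` sits within ``eps`` of 0 or
    of 1 at frame ``t``; ``is_on`` marks the 1-plateaus only (so
    ``is_on`` implies ``is_plateau``).  Intermediate frames are the ramp
    transitions, ``~is_plateau``.
    """

    is_plateau: np.ndarray
    is_on: np.ndarray
    eps: float

    def __post_init__(self) -> None:
        self.is_plateau = np.asarray(self.is_plateau, dtype=bool)
        self.is_on = np.asarray(self.is_on, dtype=bool)
        if self.is_plateau.shape != self.is_on.shape:
            raise ValueError("mask shapes disagree")
        if np.any(self.is_on & ~self.is_plateau):
            raise ValueError("is_on must imply is_plateau")


def impute_last_known(traj: MarkerTrajectorySet) -> MarkerTrajectorySet:
    """Replace undetected samples by the marker's last known pose.

    A leading undetected run is back-filled from the first detection.  The
    operation is idempotent and leaves detected samples untouched; a marker
    with no detections at all is rejected.
    """
    never = ~traj.detected.any(axis=0)
    if never.any():
        bad = [traj.marker_ids[i] for i in np.flatnonzero(never)]
        raise ValueError(f"markers never detected: {bad}")
    T = traj.n_frames
    poses = traj.poses.copy()
    idx = np.where(traj.detected, np.arange(T)[:, None], -1)
    last = np.maximum.accumulate(idx, axis=0)  # last detected frame, -1 before first
    for j in range(traj.n_markers):
        first = int(np.argmax(traj.detected[:, j]))
        src = np.where(last[:, j] >= 0, last[:, j], first)
        poses[:, j, :] = poses[src, j, :]
    return replace(
        traj, poses=poses, detected=np.ones_like(traj.detected, dtype=bool)
    )


def bandpass_sos(
    fps: float, low_hz: float = 0.01, high_hz: float = 0.5, order: int = 2
) -> np.ndarray:
    """Second-order-sections Butterworth band-pass design."""
    if not 0 < low_hz < high_hz < fps / 2:
        raise ValueError(
            f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < fps/2 = {fps / 2}"
        )
    return sps.butter(order, [low_hz, high_hz], btype="band", fs=fps, output="sos")


def bandpass(
    x: np.ndarray,
    fps: float,
    low_hz: float = 0.01,
    high_hz: float = 0.5,
    order: int = 2,
    causal: bool = False,
    axis: int = 0,
) -> np.ndarray:
    """Band-pass one or more channels independently.

    The channel mean is subtracted before filtering (the filter's DC zero
    removes any constant in steady state; removing it up front also kills
    the DC edge transient), then a zero-phase forward-backward pass with
    odd-reflection padding of length ``3 * (order + 1)`` is applied.  With
    ``causal=True`` a single forward pass is used instead (phase lag is then
    not compensated).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    padlen = 3 * (order + 1)
    if n <= padlen:
        raise ValueError(f"signal too short ({n} samples) for padding {padlen}")
    sos = bandpass_sos(fps, low_hz, high_hz, order)
    centered = x - np.mean(x, axis=axis, keepdims=True)
    if causal:
        return sps.sosfilt(sos, centered, axis=axis)
    return sps.sosfiltfilt(sos, centered, axis=axis, padtype="odd", padlen=padlen)


def build_features(
    traj: MarkerTrajectorySet,
    marker_subset: Optional[Sequence[int]] = None,
    low_hz: float = 0.01,
    high_hz: float = 0.5,
    order: int = 2,
    causal: bool = False,
) -> FeatureMatrix:
    """Filter every pose channel and stack them into the regression input X.

    ``marker_subset`` restricts the features to the given marker ids (in the
    given order), e.g. the six most proximal markers for the simulated-
    amputee analysis; X then has ``6 * len(subset)`` columns.
    """
    if not traj.detected.all():
        raise ValueError(
            "trajectory contains undetected samples; run impute_last_known first"
        )
    if marker_subset is not None:
        traj = traj.subset(tuple(marker_subset))
    T, M = traj.n_frames, traj.n_markers
    raw = traj.poses.reshape(T, M * 6)
    filtered = bandpass(raw, traj.fps, low_hz, high_hz, order, causal=causal)
    # exact re-centering: finite-length filtering leaves a tiny residual mean
    filtered = filtered - filtered.mean(axis=0, keepdims=True)
    return FeatureMatrix(X=filtered, fps=traj.fps, marker_ids=traj.marker_ids)


def onoff_mask(stimulus: StimulusProfile, eps: float = 1e-6) -> OnOffMask:
    """Label plateau vs intermediate frames, per DOF.

    A frame is a plateau frame for DOF ``d`` when that DOF's value is within
    ``eps`` of 0 or of 1 — so a frame can be "on-off" for the resting DOFs
    while another DOF is mid-ramp.
    """
    v = stimulus.values
    is_on = np.abs(v - 1.0) <= eps
    is_plateau = is_on | (np.abs(v) <= eps)
    return OnOffMask(is_plateau=is_plateau, is_on=is_on, eps=eps)
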