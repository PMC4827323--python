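"""Synthetic stimulus and forearm-deformation generator.

The generator emulates the psychophysical recording the pipeline was built
for: a subject follows a visual stimulus cueing four finger movements one at
a time (thumb rotation, thumb flexion, index flexion, combined
little/ring/middle flexion), each cued as a square-sinusoidal activation —
a raised-cosine ramp from 0 to 1, a hold at full flexion, a ramp back —
lasting 5 s with 3 s rest, the whole sequence repeated five times at
15 frames/s.  Ten fiducial markers in a 5 x 2 grid (row 0 most proximal)
deform quasi-linearly with the activations, on top of a static baseline
pose, slow sinusoidal drift, white tracking noise, and random detection
dropout.

Frames are stamped at exposure midpoints, ``t = (n + 1/2) / fps``, so the
number of frames sampled inside any plateau of duration ``p`` is
``round(fps * p)`` for generic ramp lengths.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from .config import DeformationConfig, ProtocolConfig
from .io import MarkerTrajectorySet, StimulusProfile, logger

__all__ = [
    "generate_stimulus",
    "default_mixing_gain",
    "default_baselines",
    "simulate_forearm",
    "make_subject",
]


def _activation_segment(tau: np.ndarray, flexion_s: float, ramp_s: float) -> np.ndarray:
    """Raised-cosine trapezoid on [0, flexion_s), zero elsewhere."""
    a = np.zeros_like(tau)
    if ramp_s > 0:
        up = (tau >= 0) & (tau < ramp_s)
        a[up] = 0.5 * (1.0 - np.cos(np.pi * tau[up] / ramp_s))
        down = (tau >= flexion_s - ramp_s) & (tau < flexion_s)
        a[down] = 0.5 * (1.0 - np.cos(np.pi * (flexion_s - tau[down]) / ramp_s))
        hold = (tau >= ramp_s) & (tau < flexion_s - ramp_s)
        a[hold] = 1.0
    else:
        a[(tau >= 0) & (tau < flexion_s)] = 1.0
    return a


def generate_stimulus(config: ProtocolConfig) -> StimulusProfile:
    """Generate the sequential square-sinusoidal activation profile.

    For every repetition the DOFs are activated in their listed order; each
    activation ramps 0 -> 1 over ``ramp_s`` (half-cosine), holds 1 for
    ``flexion_s - 2 * ramp_s``, ramps back, then rests at 0 for ``rest_s``.
    With ``ramp_s = 0`` the profile degenerates to a pure square wave.
    """
    T = config.n_frames
    t = (np.arange(T) + 0.5) / config.fps
    values = np.zeros((T, config.n_dofs))
    for r in range(config.repetitions):
        for d in range(config.n_dofs):
            start = config.lead_in_s + (r * config.n_dofs + d) * config.cycle_s
            values[:, d] += _activation_segment(t - start, config.flexion_s, config.ramp_s)
    values = np.clip(values, 0.0, 1.0)
    return StimulusProfile(timestamps=t, values=values, dof_names=config.dof_names)


def default_baselines(config: DeformationConfig) -> np.ndarray:
    """Static camera-frame pose of each marker, shape (n_markers, 6).

    Markers sit on a regular grid roughly 30 cm below the camera, 3 cm
    between columns and 4 cm between rows; orientations are zero.
    """
    base = np.zeros((config.n_markers, 6))
    rows = np.arange(config.n_markers) // config.n_cols
    cols = np.arange(config.n_markers) % config.n_cols
    base[:, 0] = (cols - (config.n_cols - 1) / 2.0) * 0.03
    base[:, 1] = (rows - (config.n_rows - 1) / 2.0) * 0.04
    base[:, 2] = 0.30
    return base


def default_mixing_gain(
    n_markers: int,
    n_dofs: int,
    seed: int,
    n_proximal: int = 6,
    dominant_per_dof: int = 3,
    dominant_scale: float = 5e-3,
    crosstalk: float = 0.1,
) -> np.ndarray:
    """Seeded sparse activation-to-pose mixing matrix, shape (6*M, n_dofs).

    Each DOF drives a disjoint set of dominant translation channels of
    magnitude ~``dominant_scale`` (5 mm), drawn among the ``n_proximal``
    most proximal markers — the finger flexor bellies sit in the proximal
    forearm, so that is where the bulging is strongest.  All other entries
    are small cross-talk (``crosstalk`` of the dominant scale on translation
    channels; milliradian-level responses on orientation channels).
    """
    rng = np.random.default_rng(seed)
    C = 6 * n_markers
    gain = np.zeros((C, n_dofs))
    trans = np.array(
        [6 * m + j for m in range(n_markers) for j in range(3)]
    )
    ang = np.array([6 * m + j for m in range(n_markers) for j in range(3, 6)])
    gain[trans, :] = rng.normal(0.0, crosstalk * dominant_scale, (trans.size, n_dofs))
    gain[ang, :] = rng.normal(0.0, 2e-3, (ang.size, n_dofs))

    proximal_trans = np.array(
        [6 * m + j for m in range(min(n_proximal, n_markers)) for j in range(3)]
    )
    need = dominant_per_dof * n_dofs
    if need > proximal_trans.size:
        raise ValueError(
            "not enough proximal translation channels for disjoint dominant sets"
        )
    chosen = rng.choice(proximal_trans, size=need, replace=False)
    for d in range(n_dofs):
        ch = chosen[d * dominant_per_dof : (d + 1) * dominant_per_dof]
        sign = rng.choice([-1.0, 1.0], size=ch.size)
        mag = dominant_scale * (1.0 + 0.2 * rng.standard_normal(ch.size))
        gain[ch, d] = sign * np.abs(mag)
    return gain


def simulate_forearm(
    stimulus: StimulusProfile, config: DeformationConfig
) -> MarkerTrajectorySet:
    """Map an activation profile to noisy marker trajectories.

    Channel ``c`` at frame ``t`` is
    ``baseline_c + sum_d gain[c, d] * stimulus[t, d] + drift_c(t) + noise``;
    a fraction ``dropout_rate`` of (frame, marker) samples is flagged
    undetected (their stored pose keeps the simulated value — the detector
    simply produced nothing).  Identical seeds give bit-identical output.
    """
    T, D = stimulus.values.shape
    M = config.n_markers
    C = 6 * M
    gain = config.mixing_gain
    if gain is None:
        gain = default_mixing_gain(M, D, config.seed)
    gain = np.asarray(gain, dtype=float)
    if gain.shape != (C, D):
        raise ValueError(
            f"mixing_gain shape {gain.shape} incompatible with "
            f"{C} channels x {D} DOFs"
        )

    rng = np.random.default_rng(config.seed)
    t = stimulus.timestamps
    signal = stimulus.values @ gain.T  # (T, C)

    noise_sd = np.tile(np.asarray(config.noise_sd, dtype=float), M)
    drift_amp = np.tile(np.asarray(config.drift_amplitude, dtype=float), M)
    phases = rng.uniform(-np.pi, np.pi, C)
    drift = drift_amp * np.sin(
        2.0 * np.pi * t[:, None] / config.drift_period_s + phases
    )
    noise = rng.standard_normal((T, C)) * noise_sd
    baseline = default_baselines(config).reshape(1, C)

    poses = (baseline + signal + drift + noise).reshape(T, M, 6)
    detected = rng.random((T, M)) >= config.dropout_rate
    logger.debug(
        "simulated %d frames x %d markers (dropout %.3f)",
        T, M, 1.0 - detected.mean(),
    )
    return MarkerTrajectorySet(
        marker_ids=tuple(range(M)),
        timestamps=t,
        poses=poses,
        detected=detected,
        fps=1.0 / float(np.median(np.diff(t))) if T > 1 else 1.0,
    )


def make_subject(
    protocol: Optional[ProtocolConfig] = None,
    deformation: Optional[DeformationConfig] = None,
    seed: Optional[int] = None,
) -> Tuple[MarkerTrajectorySet, StimulusProfile]:
    """Generate one synthetic subject (trajectories + ground-truth stimulus).

    ``seed`` overrides ``deformation.seed`` for convenience when generating
    subject cohorts.
    """
    protocol = protocol or ProtocolConfig()
    deformation = deformation or DeformationConfig()
    if seed is not None:
        from dataclasses import replace

        deformation = replace(deformation, seed=int(seed))
    stimulus = generate_stimulus(protocol)
    traj = simulate_forearm(stimulus, deformation)
    return traj, stimulus
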