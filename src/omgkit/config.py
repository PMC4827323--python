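"""Configuration objects for the optical-myography pipeline.

Three configuration layers mirror the three stages of a study:

* :class:`ProtocolConfig` — the stimulation protocol shown to the subject
  (which movements, how long, how often).
* :class:`DeformationConfig` — how forearm-surface markers respond to those
  movements in the synthetic generator (mixing gains, tracking noise, slow
  drift, marker dropout).
* :class:`PipelineConfig` — signal-processing and learning settings
  (band-pass filter, random-feature dimensionality, hyperparameter grids,
  validation schemes).

Defaults reproduce the reference experimental conditions: four instructed
movements (thumb rotation, thumb flexion, index flexion, combined
little/ring/middle flexion), 5 s flexion + 3 s rest repeated five times,
15 frames/s, a 0.01–0.5 Hz second-order Butterworth band-pass, D = 500
random Fourier features, and log-spaced hyperparameter grids of ten values
each (lambda exponents in [-6, 0], sigma exponents in [-3, 3]).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "DEFAULT_DOF_NAMES",
    "ProtocolConfig",
    "DeformationConfig",
    "GridSpec",
    "PipelineConfig",
]

#: The four instructed movements, in stimulation order.
DEFAULT_DOF_NAMES: Tuple[str, ...] = (
    "thumb_rotation",
    "thumb_flexion",
    "index_flexion",
    "combo_flexion",
)

#: Pose channel names in storage order.
POSE_CHANNELS: Tuple[str, ...] = ("x", "y", "z", "yaw", "pitch", "roll")


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulation protocol: which movements are cued, and when.

    Parameters
    ----------
    dof_names :
        Ordered movement names; one degree of freedom (DOF) per entry.
    flexion_s :
        Duration of one activation (ramp up, hold at 1, ramp down), seconds.
    rest_s :
        Rest at 0 after each activation, seconds.
    repetitions :
        Number of times the full movement sequence ("session") is repeated.
    fps :
        Camera frame rate, frames per second.
    ramp_s :
        Duration of each raised-cosine ramp between 0 and 1, seconds.  The
        hold-at-1 plateau therefore lasts ``flexion_s - 2 * ramp_s``.
    lead_in_s :
        Optional rest period prepended before the first activation, seconds.
    """

    dof_names: Tuple[str, ...] = DEFAULT_DOF_NAMES
    flexion_s: float = 5.0
    rest_s: float = 3.0
    repetitions: int = 5
    fps: float = 15.0
    ramp_s: float = 1.0
    lead_in_s: float = 0.0

    def __post_init__(self) -> None:
        if len(self.dof_names) < 1:
            raise ValueError("at least one degree of freedom is required")
        if self.flexion_s <= 0 or self.rest_s <= 0:
            raise ValueError("flexion_s and rest_s must be positive")
        if self.ramp_s < 0:
            raise ValueError("ramp_s must be non-negative")
        if self.flexion_s <= 2 * self.ramp_s:
            raise ValueError("flexion_s must exceed twice the ramp duration")
        if self.fps <= 1:
            raise ValueError("fps must exceed 1 frame/s")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.lead_in_s < 0:
            raise ValueError("lead_in_s must be non-negative")

    @property
    def n_dofs(self) -> int:
        return len(self.dof_names)

    @property
    def cycle_s(self) -> float:
        """Duration of one activation + rest segment, seconds."""
        return self.flexion_s + self.rest_s

    @property
    def duration_s(self) -> float:
        """Total recording duration, seconds."""
        return self.lead_in_s + self.repetitions * self.n_dofs * self.cycle_s

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


# Default per-channel magnitudes (x, y, z in meters; yaw, pitch, roll in
# radians).  Tracking noise of a fiducial detector at 720p is a fraction of a
# millimeter in translation and a few milliradians in orientation; drift from
# slow arm settling is a couple of millimeters over minutes.
_DEFAULT_NOISE_SD = (3e-4, 3e-4, 3e-4, 2e-3, 2e-3, 2e-3)
_DEFAULT_DRIFT_AMPLITUDE = (2e-3, 2e-3, 2e-3, 5e-3, 5e-3, 5e-3)


@dataclass(frozen=True)
class DeformationConfig:
    """Synthetic forearm-surface response to movement activations.

    The generated signal of each pose channel is
    ``baseline + gain @ activation + drift + white noise`` with i.i.d.
    per-(frame, marker) dropout.

    Parameters
    ----------
    n_markers :
        Number of fiducial markers; laid out ``n_rows x n_cols`` with row 0
        the most proximal (closest to the elbow).
    mixing_gain :
        Optional ``(6 * n_markers, n_dofs)`` matrix mapping unit activation
        to pose displacement (meters or radians).  When omitted, a seeded
        sparse default is drawn (see :func:`omgkit.synth.default_mixing_gain`).
    noise_sd :
        White tracking-noise SD, one value per pose channel
        (x, y, z, yaw, pitch, roll), broadcast over markers.
    drift_amplitude :
        Amplitude of the slow sinusoidal drift per pose channel.
    drift_period_s :
        Drift period, seconds; kept well above 100 s so the 0.01 Hz
        high-pass edge removes it.
    dropout_rate :
        Probability that a (frame, marker) sample is flagged undetected.
    seed :
        Seed for all generator randomness (gains, noise, drift phases,
        dropout).
    """

    n_markers: int = 10
    n_rows: int = 5
    n_cols: int = 2
    mixing_gain: Optional[np.ndarray] = None
    noise_sd: Tuple[float, ...] = _DEFAULT_NOISE_SD
    drift_amplitude: Tuple[float, ...] = _DEFAULT_DRIFT_AMPLITUDE
    drift_period_s: float = 200.0
    dropout_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.n_rows * self.n_cols != self.n_markers:
            raise ValueError("n_rows * n_cols must equal n_markers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")
        for name in ("noise_sd", "drift_amplitude"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.shape != (6,):
                raise ValueError(f"{name} must have one value per pose channel (6)")
            if np.any(vals < 0):
                raise ValueError(f"{name} entries must be >= 0")


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grids for the regularizer lambda and RFF bandwidth sigma.

    Both grids are log-spaced: ten equally spaced exponents in [-6, 0] for
    lambda and ten equally spaced exponents in [-3, 3] for sigma, giving a
    10 x 10 = 100-pair grid for the random-feature model.
    """

    lambdas: Tuple[float, ...] = tuple(np.logspace(-6.0, 0.0, 10))
    sigmas: Tuple[float, ...] = tuple(np.logspace(-3.0, 3.0, 10))

    def __post_init__(self) -> None:
        if len(self.lambdas) < 1 or len(self.sigmas) < 1:
            raise ValueError("grids must contain at least one value")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambda values must be >= 0")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigma values must be > 0")

    @classmethod
    def from_exponents(
        cls,
        lambda_exponents: Sequence[float] = (-6.0, 0.0),
        lambda_points: int = 10,
        sigma_exponents: Sequence[float] = (-3.0, 3.0),
        sigma_points: int = 10,
    ) -> "GridSpec":
        """Build log-spaced grids from exponent ranges (base 10)."""
        lo, hi = lambda_exponents
        slo, shi = sigma_exponents
        return cls(
            lambdas=tuple(np.logspace(lo, hi, lambda_points)),
            sigmas=tuple(np.logspace(slo, shi, sigma_points)),
        )

    @property
    def n_pairs(self) -> int:
        """Size of the full (lambda, sigma) product grid."""
        return len(self.lambdas) * len(self.sigmas)


@dataclass(frozen=True)
class PipelineConfig:
    """Signal-processing and learning settings for evaluation runs."""

    low_hz: float = 0.01
    high_hz: float = 0.5
    filter_order: int = 2
    causal: bool = False
    D: int = 500
    grid: GridSpec = field(default_factory=GridSpec)
    schemes: Tuple[int, ...] = (1, 2, 3, 4, 5)
    methods: Tuple[str, ...] = ("rr", "rrff")
    seed: int = 0
    marker_subset: Optional[Tuple[int, ...]] = None
    paired: bool = False
    clip: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("require 0 < low_hz < high_hz")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.D < 1:
            raise ValueError("D must be >= 1")
        bad = set(self.schemes) - {1, 2, 3, 4, 5}
        if bad:
            raise ValueError(f"unknown scheme ids: {sorted(bad)}")
        badm = set(self.methods) - {"rr", "rrff"}
        if badm:
            raise ValueError(f"unknown methods: {sorted(badm)}")
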