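"""Robustness procedures: optical perturbations and marker trimming.

Two families of stress tests probe how the pipeline degrades:

* **Optical perturbations** on the camera images feeding the fiducial
  detector — an affine brightness/contrast change ``f~(x, y) = alpha *
  f(x, y) + beta`` and Gaussian blurring with kernels up to 29 pixels.
  Because the repository does not reimplement tag decoding, the image path
  requires a user-supplied detector adapter (perturbed frames in,
  trajectories out); the perturbation operators themselves are exact and
  fully testable offline.
* **Marker trimming** ("simulated amputee") — restricting the feature set
  to the most proximal markers, emulating the shorter tracking surface of a
  residual limb, and re-running the most realistic validation scheme
  (contiguous folds, train on plateau frames, predict everything).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import GridSpec
from .io import MarkerTrajectorySet, StimulusProfile, logger
from .preprocess import build_features, impute_last_known
from .validate import run_scheme

__all__ = [
    "PerturbationSpec",
    "TrimSpec",
    "adjust_contrast_brightness",
    "gaussian_blur",
    "trim_proximal",
    "robustness_sweep",
    "read_image",
    "write_image",
]

#: adapter signature: sequence of images -> MarkerTrajectorySet
DetectorAdapter = Callable[[Sequence[np.ndarray]], MarkerTrajectorySet]


@dataclass(frozen=True)
class PerturbationSpec:
    """One optical-perturbation setting.

    ``blur_kernel`` is the side of the Gaussian kernel in pixels (odd;
    1 = no blur; the reference sweep goes up to 29), ``alpha`` scales the
    contrast (1 = original, 0.2 = 20% of the original contrast), ``beta``
    shifts the brightness in pixel units (negative = underexposure).
    """

    blur_kernel: int = 1
    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.blur_kernel < 1 or self.blur_kernel % 2 == 0:
            raise ValueError("blur_kernel must be an odd integer >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")

    def apply(self, image: np.ndarray) -> np.ndarray:
        out = adjust_contrast_brightness(image, self.alpha, self.beta)
        return gaussian_blur(out, self.blur_kernel)

    def label(self) -> str:
        return f"blur{self.blur_kernel}_alpha{self.alpha:g}_beta{self.beta:g}"


@dataclass(frozen=True)
class TrimSpec:
    """Trajectory-level setting: keep the ``n_markers`` most proximal markers."""

    n_markers: int

    def label(self) -> str:
        return f"proximal{self.n_markers}"


def adjust_contrast_brightness(
    image: np.ndarray, alpha: float, beta: float
) -> np.ndarray:
    """Affine pixel transform ``alpha * f + beta``, clipped to [0, 255].

    Integer inputs are rounded back to their dtype; float inputs stay float.
    Before clipping the operator is affine, so applying (a1, b1) then
    (a2, b2) equals applying (a1*a2, a2*b1 + b2).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    image = np.asarray(image)
    if image.min() < 0 or image.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    out = alpha * image.astype(float) + beta
    out = np.clip(out, 0.0, 255.0)
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).astype(image.dtype)
    return out


def _gaussian_kernel(k: int) -> np.ndarray:
    # sigma = k / 6 puts the +-3 sigma support inside the kernel
    sigma = k / 6.0
    r = np.arange(k) - (k - 1) / 2.0
    g = np.exp(-0.5 * (r / sigma) ** 2)
    kern = np.outer(g, g)
    return kern / kern.sum()


def gaussian_blur(image: np.ndarray, kernel_size: int) -> np.ndarray:
    """Convolve with a normalized k x k Gaussian (sigma = k/6), reflected
    borders.  ``kernel_size`` must be odd; 1 is the identity."""
    k = int(kernel_size)
    if k < 1 or k % 2 == 0:
        raise ValueError("kernel size must be an odd integer >= 1")
    image = np.asarray(image)
    if k > min(image.shape[:2]):
        raise ValueError("kernel larger than image")
    if k == 1:
        return image.copy()
    from scipy import ndimage

    out = ndimage.convolve(image.astype(float), _gaussian_kernel(k), mode="reflect")
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(np.clip(out, 0, 255)).astype(image.dtype)
    return out


def trim_proximal(traj: MarkerTrajectorySet, n: int = 6) -> MarkerTrajectorySet:
    """Keep the ``n`` most proximal markers (marker order is proximal-first,
    so rows 0-2 of the 5 x 2 grid for n = 6).  Frames are untouched."""
    if n < 1 or n > traj.n_markers:
        raise ValueError(f"n must lie in [1, {traj.n_markers}]")
    return traj.subset(traj.marker_ids[:n])


def robustness_sweep(
    traj: MarkerTrajectorySet,
    stimulus: StimulusProfile,
    specs: Sequence[Union[PerturbationSpec, TrimSpec]] = (),
    scheme: int = 5,
    method: str = "rr",
    grid: Optional[GridSpec] = None,
    seed: int = 0,
    D: int = 500,
    images: Optional[Sequence[np.ndarray]] = None,
    detector: Optional[DetectorAdapter] = None,
    low_hz: float = 0.01,
    high_hz: float = 0.5,
    order: int = 2,
) -> pd.DataFrame:
    """Evaluate the pipeline under a list of perturbation/trim settings.

    Always includes a baseline (untouched) entry.  Trim settings operate on
    the trajectories directly; image-level settings perturb the supplied
    frames and re-run the detector adapter, and are rejected with guidance
    when no adapter is given.  Returns a tidy frame with columns
    (setting, dof, nrmse, lambda, sigma).
    """
    grid = grid or GridSpec()

    def evaluate(t: MarkerTrajectorySet, label: str) -> List[dict]:
        feats = build_features(
            impute_last_known(t), low_hz=low_hz, high_hz=high_hz, order=order
        )
        rows = run_scheme(feats, stimulus, scheme, method, grid, seed=seed, D=D)
        return [
            {"setting": label, "dof": r.dof, "nrmse": r.mean_nrmse,
             "lambda": r.lam, "sigma": r.sigma}
            for r in rows
        ]

    records = evaluate(traj, "baseline")
    for spec in specs:
        if isinstance(spec, TrimSpec):
            records += evaluate(trim_proximal(traj, spec.n_markers), spec.label())
        elif isinstance(spec, PerturbationSpec):
            if images is None or detector is None:
                raise ValueError(
                    "image-level perturbations need both an image sequence and "
                    "a detector adapter (frames -> MarkerTrajectorySet); supply "
                    "them or use TrimSpec settings for the trajectory-level path"
                )
            perturbed = [spec.apply(im) for im in images]
            records += evaluate(detector(perturbed), spec.label())
        else:
            raise TypeError(f"unknown spec type: {type(spec).__name__}")
    df = pd.DataFrame(records)
    logger.info("robustness sweep: %d settings evaluated", df["setting"].nunique())
    return df


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a grayscale or RGB image (PNG) as a numpy array."""
    import imageio.v3 as iio

    return iio.imread(path)


def write_image(path: Union[str, Path], image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image))
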