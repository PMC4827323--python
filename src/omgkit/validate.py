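"""Validation schemes, hyperparameter grid search, NRMSE, and aggregation.

Five ways of splitting a recording are implemented, of increasing realism:

1. 10-fold cross-validation with shuffling over **all** frames.
2. 10-fold cross-validation with shuffling over the **plateau** (on-off)
   frames only.
3. Train on all plateau frames, test on all intermediate (ramp) frames —
   a single split, grid search without cross-validation.
4. 5-fold cross-validation over contiguous, unshuffled fifths (one
   repetition per fold under the default protocol).
5. Contiguous fifths; train on the plateau frames of four folds, test on
   **all** frames of the held-out fold — the closest to prosthetic use.

Hyperparameters are grid-searched per degree of freedom (10 lambdas for the
linear model; the 10 x 10 lambda-sigma product, 100 pairs, for the
random-feature model); the selected point is the argmin of the fold-mean
NRMSE, and that same CV error is reported (no nested CV — the resulting
optimistic bias is documented in the README).  The error metric is the root
mean squared error normalized by the target range, which equals plain RMSE
for a [0, 1] stimulus.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .config import GridSpec
from .io import StimulusProfile, logger
from .preprocess import FeatureMatrix, OnOffMask, onoff_mask
from .regress import _augment, _solve_ridge, draw_rff, rff_map

__all__ = [
    "SplitPlan",
    "GridSearchResult",
    "SchemeResult",
    "ValidationReport",
    "nrmse",
    "make_split_plan",
    "grid_search",
    "run_scheme",
    "aggregate",
    "ttest_two_tailed",
]


def nrmse(y_hat: np.ndarray, y: np.ndarray, rng: Optional[float] = None) -> float:
    """Root mean squared error normalized by the target range.

    ``rng`` defaults to ``max(y) - min(y)``; a constant target falls back to
    range 1 (so the value stays finite and equals the RMSE).
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0 or y_hat.size != y.size:
        raise ValueError("y_hat and y must be non-empty and of equal length")
    if rng is None:
        rng = float(np.max(y) - np.min(y))
        if rng == 0.0:
            rng = 1.0
    if rng <= 0:
        raise ValueError("range must be positive")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)) / rng)


@dataclass
class SplitPlan:
    """An ordered list of (train, test) index pairs for one scheme."""

    scheme_id: int
    folds: List[Tuple[np.ndarray, np.ndarray]]
    seed: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def _contiguous_folds(T: int, k: int) -> List[np.ndarray]:
    return [np.asarray(f) for f in np.array_split(np.arange(T), k)]


def make_split_plan(
    scheme_id: int,
    T: int,
    mask: Optional[OnOffMask] = None,
    dof: int = 0,
    seed: int = 0,
) -> SplitPlan:
    """Build the (train, test) pairs of one validation scheme.

    ``mask`` (with the DOF column selected by ``dof``) is required for
    schemes 2, 3, and 5, which distinguish plateau from intermediate frames.
    Shuffled schemes (1, 2) draw a seeded permutation; fold sizes differ by
    at most one; schemes 4 and 5 use contiguous, time-ordered fifths.
    """
    if scheme_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown scheme id {scheme_id}")
    need_mask = scheme_id in (2, 3, 5)
    if need_mask:
        if mask is None:
            raise ValueError(f"scheme {scheme_id} requires an on-off mask")
        plateau = np.flatnonzero(mask.is_plateau[:, dof])
        if plateau.size == 0:
            raise ValueError("on-off mask selects no plateau frames")
        if mask.is_plateau.shape[0] != T:
            raise ValueError("mask length does not match T")

    rng = np.random.default_rng(seed)
    folds: List[Tuple[np.ndarray, np.ndarray]] = []
    if scheme_id == 1:
        if T < 10:
            raise ValueError("scheme 1 needs at least 10 frames")
        perm = rng.permutation(T)
        for part in np.array_split(perm, 10):
            test = np.sort(part)
            train = np.sort(np.setdiff1d(perm, part, assume_unique=True))
            folds.append((train, test))
    elif scheme_id == 2:
        if plateau.size < 10:
            raise ValueError("scheme 2 needs at least 10 plateau frames")
        perm = rng.permutation(plateau)
        for part in np.array_split(perm, 10):
            test = np.sort(part)
            train = np.sort(np.setdiff1d(perm, part, assume_unique=True))
            folds.append((train, test))
    elif scheme_id == 3:
        intermediate = np.flatnonzero(~mask.is_plateau[:, dof])
        if intermediate.size == 0:
            raise ValueError("scheme 3 has no intermediate frames to test on")
        folds.append((plateau, intermediate))
    elif scheme_id == 4:
        if T < 5:
            raise ValueError("scheme 4 needs at least 5 frames")
        parts = _contiguous_folds(T, 5)
        for i, test in enumerate(parts):
            train = np.concatenate([p for j, p in enumerate(parts) if j != i])
            folds.append((train, test))
    else:  # scheme 5
        if T < 5:
            raise ValueError("scheme 5 needs at least 5 frames")
        parts = _contiguous_folds(T, 5)
        plateau_set = np.zeros(T, dtype=bool)
        plateau_set[plateau] = True
        for i, test in enumerate(parts):
            train = np.concatenate([p for j, p in enumerate(parts) if j != i])
            train = train[plateau_set[train]]
            if train.size == 0:
                raise ValueError("scheme 5 training folds contain no plateau frames")
            folds.append((train, test))
    return SplitPlan(scheme_id=scheme_id, folds=folds, seed=seed)


@dataclass
class GridSearchResult:
    """Outcome of one per-DOF grid search."""

    lam: float
    sigma: Optional[float]
    fold_nrmse: np.ndarray  # errors of the selected point, one per fold
    mean_nrmse: float
    n_fits: int
    errors: np.ndarray  # full (n_sigma_or_1, n_lambda) mean-error surface


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    method: str = "rr",
    grid: Optional[GridSpec] = None,
    D: int = 500,
    rff_seed: int = 0,
    y_range: Optional[float] = None,
) -> GridSearchResult:
    """Exhaustive hyperparameter search under a split plan.

    Every grid point is fitted on each training split and scored by NRMSE on
    the matching test split; fold errors are averaged and the argmin point
    returned.  The fit count is exactly ``n_grid_points * n_folds``.

    For the random-feature model, one (Omega, beta) draw is made per sigma
    (derived deterministically from ``rff_seed``) and reused across lambdas
    and folds, so lambda comparisons are not confounded by resampling noise;
    the per-fold feature Gram matrix is likewise shared across lambdas —
    each lambda still costs one full factorize-and-solve fit.
    """
    grid = grid or GridSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    method = method.lower()
    if method not in ("rr", "rrff"):
        raise ValueError(f"unknown method {method!r}")
    if y_range is None:
        y_range = float(np.max(y) - np.min(y)) or 1.0

    lambdas = np.asarray(grid.lambdas)
    sigmas = np.asarray(grid.sigmas) if method == "rrff" else np.array([np.nan])
    errors = np.zeros((sigmas.size, lambdas.size))
    n_fits = 0
    for si, sigma in enumerate(sigmas):
        if method == "rrff":
            # one frozen draw per sigma, deterministic in (rff_seed, sigma index)
            Omega, beta = draw_rff(
                X.shape[1], D, float(sigma),
                seed=(int(rff_seed) * 9973 + si) % (2**31),
            )
        fold_err = np.zeros((plan.n_folds, lambdas.size))
        for fi, (train, test) in enumerate(plan.folds):
            Xtr, Xte = X[train], X[test]
            if method == "rrff":
                Xtr = rff_map(Xtr, Omega, beta, D)
                Xte = rff_map(Xte, Omega, beta, D)
            Xtr_a, Xte_a = _augment(Xtr), _augment(Xte)
            for li, lam in enumerate(lambdas):
                w = _solve_ridge(Xtr_a, y[train], float(lam))
                n_fits += 1
                fold_err[fi, li] = nrmse(Xte_a @ w, y[test], y_range)
        errors[si] = fold_err.mean(axis=0)
        if si == 0 or np.nanmin(errors[si]) < best_sigma_err:
            best_sigma_err = float(np.nanmin(errors[si]))
            best_fold_err = fold_err
    if np.all(np.isnan(errors)):
        raise ValueError("grid search produced no finite errors (degenerate data)")
    flat = np.nanargmin(errors)
    si, li = np.unravel_index(flat, errors.shape)
    result = GridSearchResult(
        lam=float(lambdas[li]),
        sigma=None if method == "rr" else float(sigmas[si]),
        fold_nrmse=best_fold_err[:, li].copy(),
        mean_nrmse=float(errors[si, li]),
        n_fits=n_fits,
        errors=errors,
    )
    logger.debug(
        "grid search %s: lam=%.3g sigma=%s nrmse=%.4f (%d fits)",
        method, result.lam, result.sigma, result.mean_nrmse, n_fits,
    )
    return result


@dataclass
class SchemeResult:
    """Per-(scheme, method, DOF) validation outcome."""

    scheme: int
    method: str
    dof: str
    lam: float
    sigma: Optional[float]
    fold_nrmse: np.ndarray
    mean_nrmse: float
    n_fits: int


@dataclass
class ValidationReport:
    """Collection of scheme results, serializable to tidy CSV / JSON."""

    rows: List[SchemeResult] = field(default_factory=list)
    subject: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            for fold, err in enumerate(r.fold_nrmse):
                recs.append(
                    {
                        "subject": self.subject, "scheme": r.scheme,
                        "method": r.method, "dof": r.dof, "fold": fold,
                        "nrmse": err, "lambda": r.lam, "sigma": r.sigma,
                    }
                )
        return pd.DataFrame(recs)

    def mean_nrmse(self, scheme: Optional[int] = None,
                   method: Optional[str] = None) -> float:
        sel = [
            r.mean_nrmse for r in self.rows
            if (scheme is None or r.scheme == scheme)
            and (method is None or r.method == method)
        ]
        if not sel:
            raise ValueError("no matching rows")
        return float(np.mean(sel))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        self.to_frame().to_json(path, orient="records", indent=1)


def run_scheme(
    features: FeatureMatrix,
    stimulus: StimulusProfile,
    scheme: int,
    method: str = "rr",
    grid: Optional[GridSpec] = None,
    seed: int = 0,
    D: int = 500,
    eps: float = 1e-6,
) -> List[SchemeResult]:
    """Grid-searched evaluation of one scheme/method over all DOFs.

    One independent model (and hyperparameter optimum) per degree of
    freedom.  The NRMSE normalization range is taken from the full stimulus
    column (1 for a standard [0, 1] protocol) so folds are comparable.
    Deterministic given (data, seed).
    """
    if features.n_frames != stimulus.n_frames:
        raise ValueError("features and stimulus are not frame-aligned")
    grid = grid or GridSpec()
    mask = onoff_mask(stimulus, eps)
    out: List[SchemeResult] = []
    for d, dof in enumerate(stimulus.dof_names):
        y = stimulus.values[:, d]
        plan = make_split_plan(scheme, features.n_frames, mask, dof=d, seed=seed)
        y_range = float(np.max(y) - np.min(y)) or 1.0
        res = grid_search(
            features.X, y, plan, method=method, grid=grid, D=D,
            rff_seed=seed, y_range=y_range,
        )
        out.append(
            SchemeResult(
                scheme=scheme, method=method, dof=dof, lam=res.lam,
                sigma=res.sigma, fold_nrmse=res.fold_nrmse,
                mean_nrmse=res.mean_nrmse, n_fits=res.n_fits,
            )
        )
        logger.info(
            "scheme %d %s %s: nrmse=%.4f lam=%.3g sigma=%s",
            scheme, method, dof, res.mean_nrmse, res.lam, res.sigma,
        )
    return out


def evaluate_subject(
    traj,
    stimulus: StimulusProfile,
    schemes: Sequence[int] = (1, 2, 3, 4, 5),
    methods: Sequence[str] = ("rr", "rrff"),
    grid: Optional[GridSpec] = None,
    seed: int = 0,
    D: int = 500,
    marker_subset: Optional[Sequence[int]] = None,
    low_hz: float = 0.01,
    high_hz: float = 0.5,
    order: int = 2,
    causal: bool = False,
    subject: Optional[str] = None,
) -> ValidationReport:
    """Full single-subject evaluation: impute, filter, run schemes x methods."""
    from .preprocess import build_features, impute_last_known

    feats = build_features(
        impute_last_known(traj), marker_subset=marker_subset,
        low_hz=low_hz, high_hz=high_hz, order=order, causal=causal,
    )
    logger.info("feature width: %d columns", feats.n_features)
    report = ValidationReport(subject=subject)
    for scheme in schemes:
        for method in methods:
            report.rows.extend(
                run_scheme(feats, stimulus, scheme, method, grid, seed=seed, D=D)
            )
    return report


def aggregate(reports: Sequence[ValidationReport]) -> pd.DataFrame:
    """Cross-subject summary: mean, SD (n-1 denominator), SEM = SD/sqrt(n).

    One row per (scheme, method, dof), aggregating each subject's fold-mean
    NRMSE.
    """
    if len(reports) < 2:
        raise ValueError("aggregation needs at least two subjects")
    recs = []
    for rep in reports:
        for r in rep.rows:
            recs.append(
                {"scheme": r.scheme, "method": r.method, "dof": r.dof,
                 "nrmse": r.mean_nrmse}
            )
    df = pd.DataFrame(recs)
    agg = (
        df.groupby(["scheme", "method", "dof"], sort=True)["nrmse"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    agg["sem"] = agg["sd"] / np.sqrt(agg["n"])
    return agg


def ttest_two_tailed(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> Tuple[float, float]:
    """Two-tailed Student t-test between two error samples.

    Pooled-variance (classical) by default; ``welch=True`` drops the
    equal-variance assumption, ``paired=True`` uses the paired statistic.
    Two degenerate zero-variance samples with equal means give (0, 1) by
    convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal sample sizes")
        t, p = sstats.ttest_rel(a, b)
    else:
        t, p = sstats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
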