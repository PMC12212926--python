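"""Parameter -> bandpower-change response surfaces.

Gaussian-process regression maps stimulation parameter vectors to percent
change in bandpower. Kernel configuration (mean function x covariance
function) is chosen by cross-validated normalized mean squared error across
subjects; the final fit removes gross outliers (residuals beyond three
residual standard deviations from the posterior mean) and refits.

Also hosts the entrainment-vs-frequency analysis: per discrete stimulation
frequency, a one-sided Wilcoxon test of whether the percent change in the
canonical band nearest that frequency has median greater than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    ExpSineSquared,
    Kernel,
    Matern,
    RationalQuadratic,
    StationaryKernelMixin,
    WhiteKernel,
    Hyperparameter,
)
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "MEAN_FUNCTIONS",
    "COV_FUNCTIONS",
    "GaborKernel",
    "SurfaceModel",
    "select_kernel",
    "fit_surface",
    "predict_surface",
    "entrainment_vs_frequency",
]

MEAN_FUNCTIONS = ("constant", "affine")
COV_FUNCTIONS = (
    "matern",
    "periodic",
    "rational_quadratic",
    "squared_exponential",
    "gabor",
    "linear",
    "polynomial",
)


class GaborKernel(StationaryKernelMixin, Kernel):
    """Gabor covariance: squared-exponential envelope times a cosine.

    k(x, x') = exp(-||x-x'||^2 / (2 l^2)) * cos(2 pi sum(x-x') / p)
    """

    def __init__(
        self,
        length_scale: float = 1.0,
        period: float = 1.0,
        length_scale_bounds=(1e-3, 1e3),
        period_bounds=(1e-2, 1e3),
    ):
        self.length_scale = length_scale
        self.period = period
        self.length_scale_bounds = length_scale_bounds
        self.period_bounds = period_bounds

    @property
    def hyperparameter_length_scale(self):
        return Hyperparameter("length_scale", "numeric", self.length_scale_bounds)

    @property
    def hyperparameter_period(self):
        return Hyperparameter("period", "numeric", self.period_bounds)

    def __call__(self, X, Y=None, eval_gradient=False):
        X = np.atleast_2d(X)
        Y_ = X if Y is None else np.atleast_2d(Y)
        diff = X[:, None, :] - Y_[None, :, :]
        sq = np.sum(diff**2, axis=-1)
        s = np.sum(diff, axis=-1)
        env = np.exp(-sq / (2 * self.length_scale**2))
        phase = 2 * np.pi * s / self.period
        K = env * np.cos(phase)
        if not eval_gradient:
            return K
        if Y is not None:
            raise ValueError("gradient only evaluated for Y=None")
        # gradients w.r.t. log(length_scale) and log(period)
        dK_dl = env * (sq / self.length_scale**2) * np.cos(phase)
        dK_dp = env * np.sin(phase) * phase
        return K, np.dstack([dK_dl, dK_dp])

    def diag(self, X):
        return np.ones(np.atleast_2d(X).shape[0])

    def __repr__(self):
        return (
            f"GaborKernel(length_scale={self.length_scale:.3g}, "
            f"period={self.period:.3g})"
        )


def _base_kernel(cov_fn: str) -> Kernel:
    if cov_fn == "matern":
        return Matern(length_scale=1.0, nu=2.5)
    if cov_fn == "periodic":
        return ExpSineSquared(length_scale=1.0, periodicity=1.0)
    if cov_fn == "rational_quadratic":
        return RationalQuadratic(length_scale=1.0, alpha=1.0)
    if cov_fn == "squared_exponential":
        return RBF(length_scale=1.0)
    if cov_fn == "gabor":
        return GaborKernel()
    if cov_fn == "linear":
        return DotProduct(sigma_0=1.0)
    if cov_fn == "polynomial":
        return DotProduct(sigma_0=1.0) ** 2
    raise ValueError(f"unknown covariance function {cov_fn!r}")


def _make_kernel(cov_fn: str, y_var: float = 1.0) -> Kernel:
    # scale the signal/noise variances to the target so the marginal-likelihood
    # optimizer starts in the right basin
    v = max(float(y_var), 1e-12)
    return ConstantKernel(v, (1e-6 * v, 1e6 * v)) * _base_kernel(cov_fn) + WhiteKernel(
        noise_level=1e-2 * v, noise_level_bounds=(1e-12 * v, 1e3 * v)
    )


@dataclass
class SurfaceModel:
    """Fitted parameter -> percent-change surface."""

    mean_fn: str
    cov_fn: str
    gp: GaussianProcessRegressor
    x_mean: np.ndarray
    x_scale: np.ndarray
    trend: LinearRegression | None
    y_offset: float
    X_train: np.ndarray
    y_train: np.ndarray
    outlier_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) / self.x_scale

    def _mean(self, X: np.ndarray) -> np.ndarray:
        if self.trend is not None:
            return self.trend.predict(self._transform(X))
        return np.full(np.atleast_2d(X).shape[0], self.y_offset)

    def predict(self, X: np.ndarray, return_std: bool = False):
        Xs = self._transform(X)
        if return_std:
            mu, sd = self.gp.predict(Xs, return_std=True)
            return mu + self._mean(X), sd
        return self.gp.predict(Xs) + self._mean(X)


def _fit_once(
    X: np.ndarray, y: np.ndarray, mean_fn: str, cov_fn: str, seed: int | None
) -> SurfaceModel:
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale
    trend = None
    if mean_fn == "affine":
        trend = LinearRegression().fit(Xs, y)
        resid = y - trend.predict(Xs)
        y_offset = 0.0
    elif mean_fn == "constant":
        y_offset = float(y.mean())
        resid = y - y_offset
    else:
        raise ValueError(f"unknown mean function {mean_fn!r}")
    gp = GaussianProcessRegressor(
        kernel=_make_kernel(cov_fn, np.var(resid)),
        alpha=1e-10,
        normalize_y=False,
        n_restarts_optimizer=2,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(Xs, resid)
    return SurfaceModel(
        mean_fn=mean_fn,
        cov_fn=cov_fn,
        gp=gp,
        x_mean=x_mean,
        x_scale=x_scale,
        trend=trend,
        y_offset=y_offset,
        X_train=X,
        y_train=y,
    )


def select_kernel(
    datasets: Sequence[tuple[np.ndarray, np.ndarray]],
    candidates: Sequence[tuple[str, str]] | None = None,
    folds: int = 5,
    seed: int | None = 0,
) -> tuple[str, str]:
    """Choose the mean/covariance pair with lowest cross-validated NMSE.

    ``datasets`` holds one (X, y) table per subject; the per-candidate NMSE
    (mean squared error divided by target variance) is averaged over folds
    and then over subjects.
    """
    if len(datasets) == 0:
        raise ValueError("select_kernel requires at least one dataset")
    if len(datasets) == 1:
        warnings.warn("kernel selection from a single subject's data")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if candidates is None:
        candidates = [(m, c) for m in MEAN_FUNCTIONS for c in COV_FUNCTIONS]

    for X, y in datasets:
        if np.var(np.asarray(y, float)) < 1e-15:
            warnings.warn("degenerate (constant-target) dataset; falling back")
            return "constant", "linear"

    scores = {}
    for mean_fn, cov_fn in candidates:
        nmses = []
        for X, y in datasets:
            X = np.atleast_2d(np.asarray(X, float))
            y = np.asarray(y, float)
            kf = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
            sse, n_test = 0.0, 0
            for train_idx, test_idx in kf.split(X):
                model = _fit_once(X[train_idx], y[train_idx], mean_fn, cov_fn, seed)
                pred = model.predict(X[test_idx])
                sse += float(np.sum((pred - y[test_idx]) ** 2))
                n_test += test_idx.size
            nmses.append((sse / n_test) / float(np.var(y)))
        scores[(mean_fn, cov_fn)] = float(np.mean(nmses))
    return min(scores, key=scores.get)


def _loo_residuals(model: SurfaceModel) -> np.ndarray:
    """Leave-one-out residuals of the fitted GP in closed form.

    r_i = (K^-1 r)_i / (K^-1)_ii, where K includes the fitted noise term.
    In-sample residuals are useless for outlier detection when the
    marginal-likelihood optimum interpolates the outliers; the LOO form is
    the residual of each point from the GP fit to the remaining points.
    """
    from scipy.linalg import cho_solve

    gp = model.gp
    n = gp.X_train_.shape[0]
    k_inv = cho_solve((gp.L_, True), np.eye(n), check_finite=False)
    alpha = gp.alpha_.ravel()
    return alpha / np.diag(k_inv)


def fit_surface(
    X: np.ndarray,
    y: np.ndarray,
    kernel_choice: tuple[str, str] = ("affine", "matern"),
    *,
    outlier_sd: float = 3.0,
    seed: int | None = 0,
) -> SurfaceModel:
    """Two-pass GP fit with residual-based outlier removal.

    Points whose first-pass residual from the posterior mean exceeds
    ``outlier_sd`` residual standard deviations are excluded and the model
    refit once. Hyperparameters are optimized by marginal-likelihood
    maximization.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if len(y) < 10:
        raise ValueError("fit_surface requires at least 10 points")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("inputs must be finite")
    mean_fn, cov_fn = kernel_choice
    first = _fit_once(X, y, mean_fn, cov_fn, seed)
    resid = _loo_residuals(first)
    sd = float(resid.std())
    if sd == 0:
        outliers = np.empty(0, int)
    else:
        outliers = np.flatnonzero(np.abs(resid) > outlier_sd * sd)
    if outliers.size == len(y):
        raise RuntimeError("all points flagged as outliers")
    if outliers.size == 0:
        first.outlier_idx = outliers
        return first
    keep = np.setdiff1d(np.arange(len(y)), outliers)
    final = _fit_once(X[keep], y[keep], mean_fn, cov_fn, seed)
    final.outlier_idx = outliers
    return final


def predict_surface(
    model: SurfaceModel, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and predictive SD on a parameter lattice."""
    mu, sd = model.predict(np.atleast_2d(grid), return_std=True)
    return mu, np.maximum(sd, 0.0)


def entrainment_vs_frequency(
    table: pd.DataFrame,
    freq_grid: Sequence[float],
    *,
    freq_col: str = "freq",
    value_col: str = "stim_band_pct",
    min_trials: int = 5,
    freq_tol: float = 0.5,
) -> pd.DataFrame:
    """Per-frequency entrainment summary with one-sided Wilcoxon tests.

    For each grid frequency, selects trials delivered at that frequency and
    tests whether the median percent change in the band containing it
    exceeds zero. Frequencies with fewer than ``min_trials`` trials are
    skipped with a warning.
    """
    rows = []
    for f in freq_grid:
        sel = table[np.isclose(table[freq_col], f, atol=freq_tol)]
        vals = sel[value_col].to_numpy(float)
        if vals.size < min_trials:
            warnings.warn(f"frequency {f} Hz has only {vals.size} trials; skipped")
            continue
        if np.allclose(vals, 0):
            p = 1.0
        else:
            p = float(wilcoxon(vals, alternative="greater").pvalue)
        rows.append(
            {
                "freq": f,
                "n": int(vals.size),
                "mean_pct": float(vals.mean()),
                "median_pct": float(np.median(vals)),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
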