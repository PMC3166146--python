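"""Scaling law relating cis-eQTL counts to sample size.

The empirical law is that the square root of the eQTL count grows linearly
in the log of the sample size:

    sqrt(q) = alpha + beta * ln(n)

fitted by ordinary least squares; extrapolation inverts the transform,
q_hat(n) = (alpha + beta * ln n)^2, valid wherever the linear predictor is
non-negative.  The functional form is pinned down by the published
coefficient table it is used with: evaluating (alpha + beta ln n)^2 at each
tissue's full sample size reproduces that table's extrapolated counts to
within coefficient-rounding error, whereas linear, log-log or exponential
alternatives are off by orders of magnitude (re-verified in the test
suite).

``ScalingLawModel`` follows the fit/predict estimator convention with
fitted attributes ``alpha_``, ``beta_``, ``r_squared_``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of sqrt(count) on ln(size)."""

    alpha: float
    beta: float
    r_squared: float
    n_points: int
    transform: str = "sqrt-count vs log-size"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a scaling fit needs at least 3 points")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (intercept, slope, R^2); constant y gives slope 0, R^2 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("all sizes identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    residual = y - (intercept + slope * x)
    ss_res = float(np.sum(residual ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float(intercept), float(slope), 0.0
    return float(intercept), float(slope), max(0.0, 1.0 - ss_res / ss_tot)


class ScalingLawModel:
    """Estimator for the sqrt(count) ~ ln(size) law.

    After ``fit(sizes, counts)`` the attributes ``alpha_`` (intercept),
    ``beta_`` (slope), ``r_squared_`` and ``n_points_`` are set;
    ``predict(n)`` returns the extrapolated count (alpha_ + beta_ ln n)^2.
    """

    def fit(self, sizes, counts) -> "ScalingLawModel":
        sizes = np.asarray(sizes, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if sizes.shape != counts.shape or sizes.ndim != 1:
            raise ValueError("sizes and counts must be equal-length 1-D arrays")
        if sizes.size < 3:
            raise ValueError("need at least 3 (size, count) points")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (sizes < 2).any():
            raise ValueError("sizes must be >= 2")
        alpha, beta, r2 = _ols_line(np.log(sizes), np.sqrt(counts))
        self.alpha_ = alpha
        self.beta_ = beta
        self.r_squared_ = r2
        self.n_points_ = int(sizes.size)
        return self

    def predict(self, n) -> np.ndarray | float:
        self._check_fitted()
        return _predict(self.alpha_, self.beta_, n)

    def predict_count(self, n: float) -> int:
        self._check_fitted()
        return predict_count((self.alpha_, self.beta_), n)

    def to_fit(self) -> ScalingFit:
        self._check_fitted()
        return ScalingFit(self.alpha_, self.beta_, self.r_squared_,
                          self.n_points_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "alpha_"):
            raise AttributeError("model is not fitted; call fit() first")


def fit_scaling_law(sizes, counts) -> ScalingFit:
    """OLS of sqrt(counts) on ln(sizes); returns (alpha, beta, R^2)."""
    return ScalingLawModel().fit(sizes, counts).to_fit()


def _predict(alpha: float, beta: float, n) -> np.ndarray | float:
    n_arr = np.asarray(n, dtype=float)
    linear = alpha + beta * np.log(n_arr)
    if np.any(linear < 0):
        if beta > 0:
            valid_from = math.exp(-alpha / beta)
            raise ValueError(
                f"negative linear predictor: the law is only valid for "
                f"n >= {valid_from:.1f} with these coefficients")
        raise ValueError("negative linear predictor for the requested n")
    result = linear ** 2
    return float(result) if np.isscalar(n) else result


def predict_count(fit, n: float) -> int:
    """Extrapolated eQTL count at sample size n, rounded half-up to integer.

    ``fit`` is a ScalingFit, a fitted ScalingLawModel, or an (alpha, beta)
    pair.
    """
    if isinstance(fit, ScalingLawModel):
        alpha, beta = fit.alpha_, fit.beta_
    elif isinstance(fit, ScalingFit):
        alpha, beta = fit.alpha, fit.beta
    else:
        alpha, beta = fit
    value = _predict(alpha, beta, float(n))
    return int(math.floor(value + 0.5))


def sliding_window_slope(sizes, counts, window: int) -> np.ndarray:
    """OLS slope of sqrt(count) on ln(size) in each window of consecutive steps.

    Returns one slope per window start (len(sizes) - window + 1 values);
    an increasing sequence signals accelerating detection, a decreasing one
    saturation.
    """
    sizes = np.asarray(sizes, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if window < 3:
        raise ValueError("window must be >= 3")
    if window > sizes.size:
        raise ValueError(f"window {window} exceeds the {sizes.size} points")
    x = np.log(sizes)
    y = np.sqrt(counts)
    slopes = []
    for start in range(sizes.size - window + 1):
        stop = start + window
        _, slope, _ = _ols_line(x[start:stop], y[start:stop])
        slopes.append(slope)
    return np.array(slopes)
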