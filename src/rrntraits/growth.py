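"""Logistic growth-curve fitting and trait-growth regression.

Cell-count time series from developing biofilms are summarized by the
Zwietering re-parameterized logistic,

    f(t) = A / (1 + exp(4 * mu_max / A * (lag - t) + 2)),

whose parameters are directly the quantities of ecological interest:
A is the carrying capacity (asymptote, in count units), mu_max the maximum
slope of the curve (count units per day), and lag the lag phase L in days —
the intercept of the tangent at the inflection point with the time axis.
Fitting is bounded nonlinear least squares on the raw counts (an optional
log transform is available) with seeded multi-start jitter; non-convergence
returns the best-so-far parameters flagged, never an exception.

Trait-growth relationships (community HCN:LCN ratio against mu_max or L)
and per-class abundance trends over time use ordinary least squares with a
95% confidence band for the mean response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "GrowthCurve",
    "GrowthFit",
    "RegressionResult",
    "zwietering_logistic",
    "fit_logistic",
    "regress_trait_growth",
    "fit_linear_trend",
]

MIN_OBSERVATIONS = 5
_EPS = 1e-12


@dataclass
class GrowthCurve:
    """A single growth time series (days, counts) with a condition label."""

    time: np.ndarray
    value: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.value.shape:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if len(self.time) < MIN_OBSERVATIONS:
            raise ValueError(f"need at least {MIN_OBSERVATIONS} observations, got {len(self.time)}")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.time < 0) or np.any(self.value < 0):
            raise ValueError("time and value must be non-negative")


@dataclass
class GrowthFit:
    A: float
    mu_max: float
    lag: float
    rss: float
    converged: bool
    n_obs: int
    label: str = ""

    def predict(self, t) -> np.ndarray:
        return zwietering_logistic(np.asarray(t, dtype=float), self.A, self.mu_max, self.lag)


def zwietering_logistic(t, A, mu_max, lag):
    """Logistic curve parameterized by asymptote, max slope, and lag."""
    z = 4.0 * mu_max / A * (lag - t) + 2.0
    return A / (1.0 + np.exp(np.clip(z, -700, 700)))


def _default_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A0 = max(float(y.max()), _EPS)
    slopes = np.diff(y) / np.diff(t)
    k = int(np.argmax(slopes))
    mu0 = max(float(slopes[k]), _EPS)
    t_steep = 0.5 * (t[k] + t[k + 1])
    lag0 = max(t_steep - A0 / (2.0 * mu0), 0.0)
    return A0, mu0, lag0


def fit_logistic(
    curve: GrowthCurve,
    init=None,
    n_restarts: int = 5,
    seed: int = 0,
    log_transform: bool = False,
) -> GrowthFit:
    """Fit the Zwietering logistic to one growth curve.

    Box bounds keep A > 0, mu_max > 0, lag >= 0. The first start uses
    ``init`` (or a finite-difference heuristic); up to ``n_restarts``
    further starts jitter it lognormally with the given seed. The best
    residual sum of squares wins. A fit that never converges, or whose
    mu_max sits at the lower bound (e.g. a constant series), is returned
    with ``converged=False``.
    """
    t, y = curve.time, curve.value
    if log_transform:
        y = np.log1p(y)
    x0 = np.array(init if init is not None else _default_init(t, y), dtype=float)
    lb = np.array([_EPS, _EPS, 0.0])
    ub = np.array([np.inf, np.inf, np.inf])
    x0 = np.clip(x0, lb + _EPS, None)

    def resid(p):
        return zwietering_logistic(t, *p) - y

    rng = np.random.default_rng(seed)
    best = None
    best_ok = False
    for trial in range(n_restarts + 1):
        start = x0 if trial == 0 else np.clip(x0 * rng.lognormal(0.0, 0.3, size=3), lb + _EPS, None)
        try:
            res = least_squares(resid, start, bounds=(lb, ub), xtol=1e-10, ftol=1e-10,
                                gtol=1e-10, max_nfev=500 * 3)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1]:
            best = (res.x, rss)
            best_ok = bool(res.success)
    if best is None:
        A0, mu0, lag0 = x0
        return GrowthFit(A0, mu0, lag0, float(np.sum(resid(x0) ** 2)), False, len(t), curve.label)
    (A, mu, lag), rss = best
    degenerate = mu <= 10 * _EPS or A <= 10 * _EPS
    # an asymptote far above every observation means the curve never
    # approached saturation in the observation window: the parameters are
    # not identifiable from these data
    extrapolated = A > 10 * max(float(y.max()), _EPS)
    converged = best_ok and not degenerate and not extrapolated and lag < t.max()
    return GrowthFit(float(A), float(mu), float(lag), rss, converged, len(t), curve.label)


@dataclass
class RegressionResult:
    """Simple OLS summary with a 95% confidence band for the mean response."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    _model: object = None

    def ci95_band(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper 95% confidence limits of the predicted mean at x."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        X = sm.add_constant(x, has_constant="add")
        pred = self._model.get_prediction(X)
        ci = pred.conf_int(alpha=0.05)
        return ci[:, 0], ci[:, 1]

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _ols(x, y) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("undefined (NaN) values are not admissible")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        # constant y gives ssr == 0; statsmodels warns on the F statistic
        warnings.simplefilter("ignore")
        model = sm.OLS(y, X).fit()
        slope = float(model.params[1])
        intercept = float(model.params[0])
        r2 = float(model.rsquared)
        p = float(model.pvalues[1])
    if np.ptp(y) == 0:
        r2, p = 0.0, 1.0
    return RegressionResult(slope, intercept, r2, p, len(x), _model=model)


def regress_trait_growth(x, y) -> RegressionResult:
    """OLS of time-averaged HCN:LCN ratios against a growth parameter.

    ``x`` holds one fitted growth parameter (mu_max or lag) per flume or
    treatment, ``y`` the matching trait averages. Returns slope,
    intercept, R^2, the two-sided slope p-value, and the 95% confidence
    band for the mean response.
    """
    return _ols(x, y)


def fit_linear_trend(time, y) -> RegressionResult:
    """OLS linear trend of an abundance series against time (days)."""
    return _ols(time, y)
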