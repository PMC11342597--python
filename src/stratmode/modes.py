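"""Maximum-likelihood identification of the mode of evolution.

Three candidate models are fitted to a population time series (sample means
``y_i`` with sampling-error variances ``eps_i = var_i / n_i`` at times
``t_i``), and compared by the small-sample corrected Akaike Information
Criterion (AICc) and Akaike weights:

* **Stasis** — ``y_i ~ Normal(theta, omega + eps_i)``, independent.
* **URW** (unbiased random walk) — Brownian motion observed with noise.
* **GRW** (general random walk) — Brownian drift observed with noise.

Two likelihood formulations are available, mirroring established practice in
paleontological time-series analysis:

* ``joint`` (default): the full multivariate normal of all observations.
  With the time origin shifted so ``t_1 = 0``, the random-walk models have
  mean ``anc + mstep * t_i`` (``mstep = 0`` for URW) and covariance
  ``vstep * min(t_i, t_j) + eps_i * 1{i=j}``.
* ``ad`` (ancestor–descendant): successive differences are treated as
  independent, ``d_i ~ Normal(mstep * dt_i, vstep * dt_i + eps_i + eps_{i+1})``;
  stasis drops the first observation and treats the rest as i.i.d. draws.

Parameter counts K and effective sample sizes n for AICc follow the
formulation: joint {Stasis 2, URW 2, GRW 3} with n = number of samples;
ad {Stasis 2, URW 1, GRW 2} with n = number of differences.

Fitting maximizes the profile likelihood: for a fixed variance parameter
(omega or vstep) the mean parameters (theta, anc, mstep) are generalized
least squares estimates in closed form, leaving a one-dimensional bounded
optimization that is solved by a log-spaced grid scan plus Brent refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import minimize_scalar

from .sampling import PhenoSeries

__all__ = [
    "MODELS",
    "FitResult",
    "ModelComparison",
    "prepare_epsilon",
    "loglik",
    "fit_model",
    "aicc",
    "akaike_weights",
    "compare_models",
    "evidence_ratio",
]

MODELS = ("Stasis", "URW", "GRW")

_LOG2PI = np.log(2.0 * np.pi)
#: relative lower bound on variance parameters (times the series variance scale)
_VAR_LB_REL = 1e-8


@dataclass(frozen=True)
class FitResult:
    """One model's maximum-likelihood fit to a series."""

    model: str
    method: str
    params: dict
    logL: float
    K: int
    n_used: int
    AICc: float
    converged: bool = True


@dataclass(frozen=True)
class ModelComparison:
    """AICc table and Akaike weights for the three candidate models."""

    fits: dict  # model name -> FitResult
    weights: dict  # model name -> Akaike weight

    @property
    def best(self) -> str:
        return max(self.weights, key=self.weights.get)

    def delta_aicc(self) -> dict:
        lo = min(f.AICc for f in self.fits.values())
        return {m: f.AICc - lo for m, f in self.fits.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "model": m,
                "logL": f.logL,
                "K": f.K,
                "n": f.n_used,
                "AICc": f.AICc,
                "weight": self.weights[m],
            }
            for m, f in self.fits.items()
        ]
        return pd.DataFrame(rows)


def prepare_epsilon(series: PhenoSeries, pool: bool = True) -> np.ndarray:
    """Sampling-error variances ``eps_i = var_i / n_i``.

    With ``pool`` (the default), all sample variances are first replaced by
    their (n_i - 1)-weighted mean, stabilizing the per-sample error estimate.
    """
    n = series.n
    if np.any(n < 2):
        raise ValueError("every sample needs n >= 2 specimens")
    var = series.sample_var.astype(float)
    if pool:
        w = n - 1
        var = np.full_like(var, float(np.sum(w * var) / np.sum(w)))
    return var / n


def _chol_mvn_loglik(resid: np.ndarray, cov: np.ndarray) -> float:
    try:
        c, low = linalg.cho_factor(cov, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    if np.any(np.diag(c) <= 0):
        return -np.inf
    alpha = linalg.cho_solve((c, low), resid, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (resid @ alpha + logdet + resid.size * _LOG2PI))


def _rw_cov(t0: np.ndarray, vstep: float, eps: np.ndarray) -> np.ndarray:
    return vstep * np.minimum.outer(t0, t0) + np.diag(eps)


def loglik(model: str, params: dict, times, means, eps, method: str = "joint") -> float:
    """Log-likelihood of a candidate model at explicit parameter values.

    ``times`` is whatever time vector the caller assumes (true deposition
    times, or positions rescaled under the uninterrupted-constant-
    accumulation convention).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(means, dtype=float)
    e = np.asarray(eps, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if method not in ("joint", "ad"):
        raise ValueError("method must be 'joint' or 'ad'")

    if model == "Stasis":
        omega = params["omega"]
        if omega < 0:
            raise ValueError("omega must be >= 0")
        theta = params["theta"]
        if method == "ad":
            y, e = y[1:], e[1:]
        v = omega + e
        if np.any(v <= 0):
            return -np.inf
        return float(-0.5 * np.sum(np.log(2 * np.pi * v) + (y - theta) ** 2 / v))

    mstep = params.get("mstep", 0.0) if model == "GRW" else 0.0
    vstep = params["vstep"]
    if vstep < 0:
        raise ValueError("vstep must be >= 0")
    if method == "joint":
        anc = params["anc"]
        t0 = t - t[0]
        resid = y - (anc + mstep * t0)
        return _chol_mvn_loglik(resid, _rw_cov(t0, vstep, e))
    d = np.diff(y)
    dt = np.diff(t)
    v = vstep * dt + e[:-1] + e[1:]
    if np.any(v <= 0):
        return -np.inf
    return float(-0.5 * np.sum(np.log(2 * np.pi * v) + (d - mstep * dt) ** 2 / v))


def _optimize_1d(nll, lb: float, ub: float, n_grid: int = 17) -> tuple[float, float]:
    """Deterministic multi-start: log grid scan + bounded Brent refinement."""
    grid = np.geomspace(lb, ub, n_grid)
    vals = np.array([nll(g) for g in grid])
    i = int(np.nanargmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    best_x, best_f = grid[i], vals[i]
    if hi > lo:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = float(res.x), float(res.fun)
    return best_x, best_f


def _fit_stasis(t, y, e, method):
    if method == "ad":
        y, e = y[1:], e[1:]
    scale = max(float(np.var(y)), float(np.mean(e)), 1e-12)
    lb = _VAR_LB_REL * scale
    ub = 100.0 * scale

    def profile(omega):
        w = 1.0 / (omega + e)
        theta = np.sum(w * y) / np.sum(w)
        v = omega + e
        return 0.5 * np.sum(np.log(2 * np.pi * v) + (y - theta) ** 2 / v)

    omega, nll = _optimize_1d(profile, lb, ub)
    w = 1.0 / (omega + e)
    theta = float(np.sum(w * y) / np.sum(w))
    return {"theta": theta, "omega": float(omega)}, -nll


def _gls(X: np.ndarray, y: np.ndarray, cov: np.ndarray):
    c, low = linalg.cho_factor(cov, lower=True, check_finite=False)
    Xi = linalg.cho_solve((c, low), X, check_finite=False)
    yi = linalg.cho_solve((c, low), y, check_finite=False)
    beta = np.linalg.solve(X.T @ Xi, X.T @ yi)
    resid = y - X @ beta
    alpha = linalg.cho_solve((c, low), resid, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    ll = -0.5 * (resid @ alpha + logdet + y.size * _LOG2PI)
    return beta, float(ll)


def _fit_rw_joint(t, y, e, with_drift):
    t0 = t - t[0]
    X = np.column_stack([np.ones_like(t0), t0]) if with_drift else np.ones((t0.size, 1))
    d = np.diff(y)
    dt = np.diff(t)
    mom = max(float(np.mean(d**2 / dt)), 1e-12)
    lb = _VAR_LB_REL * mom
    ub = 100.0 * mom

    def profile(vstep):
        try:
            _, ll = _gls(X, y, _rw_cov(t0, vstep, e))
        except linalg.LinAlgError:
            return np.inf
        return -ll

    vstep, nll = _optimize_1d(profile, lb, ub)
    beta, ll = _gls(X, y, _rw_cov(t0, vstep, e))
    params = {"anc": float(beta[0]), "vstep": float(vstep)}
    if with_drift:
        params["mstep"] = float(beta[1])
    return params, ll


def _fit_rw_ad(t, y, e, with_drift):
    d = np.diff(y)
    dt = np.diff(t)
    es = e[:-1] + e[1:]
    mom = max(float(np.mean(d**2 / dt)), 1e-12)
    lb = _VAR_LB_REL * mom
    ub = 100.0 * mom

    def profile(vstep):
        v = vstep * dt + es
        if with_drift:
            w = dt / v
            mstep = np.sum(w * d) / np.sum(dt * w)
            r = d - mstep * dt
        else:
            r = d
        return 0.5 * np.sum(np.log(2 * np.pi * v) + r**2 / v)

    vstep, nll = _optimize_1d(profile, lb, ub)
    params = {"vstep": float(vstep)}
    if with_drift:
        v = vstep * dt + es
        w = dt / v
        params["mstep"] = float(np.sum(w * d) / np.sum(dt * w))
    return params, -nll


_K_TABLE = {
    ("joint", "Stasis"): 2,
    ("joint", "URW"): 2,
    ("joint", "GRW"): 3,
    ("ad", "Stasis"): 2,
    ("ad", "URW"): 1,
    ("ad", "GRW"): 2,
}


def _series_arrays(series: PhenoSeries, pool: bool):
    """(times, means, eps) for fitting; stratigraphic positions stand in for
    time under the uninterrupted-constant-accumulation convention."""
    t = series.positions.astype(float)
    return t, series.sample_mean.astype(float), prepare_epsilon(series, pool)


def fit_model(
    series: PhenoSeries, model: str, method: str = "joint", pool: bool = True
) -> FitResult:
    """Maximum-likelihood fit of one candidate model."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if method not in ("joint", "ad"):
        raise ValueError("method must be 'joint' or 'ad'")
    t, y, e = _series_arrays(series, pool)
    n = len(series)
    if (method == "joint" and n < 4) or (method == "ad" and n < 4):
        warnings.warn(f"series of {n} samples is short for a reliable fit")
    converged = True
    try:
        if model == "Stasis":
            params, ll = _fit_stasis(t, y, e, method)
        elif method == "joint":
            params, ll = _fit_rw_joint(t, y, e, with_drift=(model == "GRW"))
        else:
            params, ll = _fit_rw_ad(t, y, e, with_drift=(model == "GRW"))
        if not np.isfinite(ll):
            converged = False
    except linalg.LinAlgError:
        params, ll, converged = {}, -np.inf, False
    K = _K_TABLE[(method, model)]
    n_used = n if method == "joint" else n - 1
    a = aicc(ll, K, n_used) if converged else np.inf
    return FitResult(model, method, params, float(ll), K, n_used, a, converged)


def aicc(logL: float, K: int, n: int) -> float:
    """Corrected AIC: ``-2 logL + 2K + 2K(K+1)/(n-K-1)``; +inf if n <= K+1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n - K - 1 <= 0:
        return np.inf
    return float(-2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1))


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ``exp(-delta_i/2) / sum_j exp(-delta_j/2)``."""
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("need at least one finite AICc value")
    delta = a - np.min(a[finite])
    w = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return w / w.sum()


def compare_models(
    series: PhenoSeries, method: str = "joint", pool: bool = True
) -> ModelComparison:
    """Fit Stasis, URW and GRW and compare them by AICc weight."""
    fits = {m: fit_model(series, m, method, pool) for m in MODELS}
    w = akaike_weights([fits[m].AICc for m in MODELS])
    return ModelComparison(fits, dict(zip(MODELS, w)))


def evidence_ratio(comparison: ModelComparison, model_a: str, model_b: str) -> float:
    """Ratio of Akaike weights w_a / w_b (+inf when w_b = 0)."""
    wa = comparison.weights[model_a]
    wb = comparison.weights[model_b]
    if wb == 0:
        return np.inf
    return wa / wb
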