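"""Learning-curve regressions of turnaround time on case number.

Two models that act as sensitivity analyses for each other:

* a robust M-estimator linear regression (Huber start, Tukey biweight
  finish, fitted by iteratively reweighted least squares), whose slope
  is the change in TAT in days per additional case; and
* a negative-binomial (NB2) count regression with a log link, whose
  exponentiated slope is the incidence-rate ratio (IRR) — the
  multiplicative change in expected TAT per additional case.

Both are implemented from their definitions here; library fits are used
only as independent cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln, digamma, polygamma

from .series import TATSeries, ValidationError

__all__ = [
    "RegressionFit",
    "fit_robust_linear",
    "fit_negative_binomial",
    "robust_linear",
    "negative_binomial",
    "nb_loglikelihood",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class RegressionFit:
    """Result of a learning-curve regression.

    ``slope`` is in days/case for the robust linear model and in
    log-rate per case for the NB model; ``irr`` (NB only) is
    ``exp(slope)``.  ``ci_low``/``ci_high`` are 95% Wald bounds on the
    reported scale: the slope scale for the robust model, the IRR scale
    for the NB model.
    """

    method: str
    slope: float
    intercept: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    irr: Optional[float] = None
    dispersion: Optional[float] = None
    n_iterations: int = 0
    converged: bool = True
    n_obs: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _check_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValidationError(f"need at least 3 cases (got {len(x)})")
    if np.ptp(x) == 0:
        raise ValidationError("case numbers are degenerate (no variation)")
    return x, y


# ---------------------------------------------------------------------------
# Robust M-estimation (Huber then Tukey biweight IRLS)
# ---------------------------------------------------------------------------

_HUBER_K = 1.345
_BIWEIGHT_C = 4.685


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares for intercept + slope; returns (b0, b1)."""
    X = np.column_stack([np.ones_like(x), x])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _scale_mad(resid: np.ndarray) -> float:
    """Normalized median absolute deviation of the residuals."""
    return stats.median_abs_deviation(resid, scale="normal")


def _huber_weights(u: np.ndarray) -> np.ndarray:
    au = np.abs(u)
    w = np.ones_like(u)
    big = au > _HUBER_K
    w[big] = _HUBER_K / au[big]
    return w

def _biweight_weights(u: np.ndarray) -> np.ndarray:
    w = (1.0 - (u / _BIWEIGHT_C) ** 2) ** 2
    w[np.abs(u) >= _BIWEIGHT_C] = 0.0
    return w


def _cooks_distance(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    p = 2
    n = len(x)
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    h = np.diag(H)
    s2 = resid @ resid / (n - p)
    if s2 == 0:
        return np.zeros(n)
    return resid**2 * h / (p * s2 * (1 - h) ** 2)


def robust_linear(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    drop_gross_outliers: bool = True,
) -> RegressionFit:
    """Robust simple linear regression of ``y`` on ``x``.

    IRLS with Huber weighting (k = 1.345 on MAD-scaled residuals) run
    to convergence, then Tukey biweight weighting (c = 4.685) run to
    convergence from the Huber solution.  Observations with Cook's
    distance > 1 under the initial OLS fit are discarded first.  The
    standard error is the weighted least-squares sandwich evaluated at
    the final weights.
    """
    x, y = _check_xy(x, y)
    keep = np.ones(len(x), dtype=bool)
    if drop_gross_outliers:
        keep = _cooks_distance(x, y) <= 1.0
        if keep.sum() < 3:
            keep = np.ones(len(x), dtype=bool)
    xk, yk = x[keep], y[keep]

    coef = _wls(xk, yk, np.ones_like(xk))
    n_iter = 0
    converged = True
    w = np.ones_like(xk)
    for weight_fn in (_huber_weights, _biweight_weights):
        stage_converged = False
        for _ in range(max_iter):
            n_iter += 1
            resid = yk - (coef[0] + coef[1] * xk)
            sigma = _scale_mad(resid)
            if sigma == 0:
                # exact fit: all weights 1, nothing left to reweight
                w = np.ones_like(xk)
                stage_converged = True
                break
            w = weight_fn(resid / sigma)
            if w.sum() == 0 or np.count_nonzero(w) < 3:
                # pathological: everything down-weighted away
                w = np.ones_like(xk)
                stage_converged = False
                break
            new_coef = _wls(xk, yk, w)
            delta = np.max(np.abs(new_coef - coef) / np.maximum(np.abs(coef), 1e-12))
            coef = new_coef
            if delta < tol:
                stage_converged = True
                break
        converged = converged and stage_converged

    resid = yk - (coef[0] + coef[1] * xk)
    X = np.column_stack([np.ones_like(xk), xk])
    A = X.T @ (X * w[:, None])
    meat = X.T @ (X * (w**2 * resid**2)[:, None])
    try:
        Ainv = np.linalg.inv(A)
        cov = Ainv @ meat @ Ainv
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
        converged = False
    slope = float(coef[1])
    ci_low, ci_high = slope - _Z975 * se, slope + _Z975 * se
    if se > 0:
        p = 2 * stats.norm.sf(abs(slope) / se)
    else:
        p = 0.0 if slope != 0 else 1.0
    return RegressionFit(
        method="robust_linear",
        slope=slope,
        intercept=float(coef[0]),
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        n_iterations=n_iter,
        converged=bool(converged),
        n_obs=int(keep.sum()),
    )


def fit_robust_linear(series: TATSeries, component: str = "overall") -> RegressionFit:
    """Robust linear learning-curve fit of a TAT component on case number."""
    y = series.component(component)
    return robust_linear(series.case_index, y)


# ---------------------------------------------------------------------------
# Negative-binomial (NB2) maximum likelihood
# ---------------------------------------------------------------------------


def nb_loglikelihood(
    beta0: float, beta1: float, dispersion: float, x: np.ndarray, y: np.ndarray
) -> float:
    """Exact NB2 log-likelihood at ``(beta0, beta1, dispersion)``.

    The mean is ``mu_i = exp(beta0 + beta1 * x_i)`` and the variance is
    ``mu_i + mu_i**2 / dispersion`` (size parameterization, k > 0).
    """
    if not dispersion > 0:
        raise ValidationError(f"dispersion must be > 0 (got {dispersion})")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = float(dispersion)
    eta = beta0 + beta1 * x
    mu = np.exp(eta)
    ll = (
        gammaln(y + k)
        - gammaln(k)
        - gammaln(y + 1)
        + k * np.log(k / (k + mu))
        + y * np.log(mu / (k + mu))
    )
    return float(np.sum(ll))


def _nb_beta_step(
    beta: np.ndarray, k: float, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """One Fisher-scoring step for the regression coefficients given k."""
    eta = X @ beta
    mu = np.exp(eta)
    w = mu / (1.0 + mu / k)  # GLM working weights for NB2, log link
    z = eta + (y - mu) / mu  # working response
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    return coef


def _nb_dll_dk(k: float, mu: np.ndarray, y: np.ndarray) -> float:
    return float(
        np.sum(digamma(y + k) - digamma(k) + np.log(k / (k + mu)) + (mu - y) / (k + mu))
    )


def _nb_d2ll_dk2(k: float, mu: np.ndarray, y: np.ndarray) -> float:
    return float(
        np.sum(
            polygamma(1, y + k)
            - polygamma(1, k)
            + 1.0 / k
            - 2.0 / (k + mu)
            + (y + k) / (k + mu) ** 2
        )
    )


def negative_binomial(
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RegressionFit:
    """NB2 maximum-likelihood regression of counts ``y`` on ``x``.

    Alternates Fisher scoring for the coefficients with safeguarded
    Newton steps for the size parameter (on the log scale), with step
    halving so the log-likelihood never decreases.  Wald standard
    errors come from the observed information at the optimum.
    """
    x, y = _check_xy(x, y)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValidationError("counts must be non-negative integers")
    if np.all(y == 0):
        raise ValidationError("all counts are zero; NB regression is undefined")
    X = np.column_stack([np.ones_like(x), x])

    # moment-based starting values
    beta = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)[0]
    mu = np.exp(X @ beta)
    excess = np.mean((y - mu) ** 2 - mu)
    k = float(np.mean(mu**2) / excess) if excess > 0 else 100.0
    k = min(max(k, 1e-3), 1e6)

    ll = nb_loglikelihood(beta[0], beta[1], k, x, y)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # coefficients given k, with step halving to keep ll monotone
        new_beta = _nb_beta_step(beta, k, X, y)
        step = new_beta - beta
        for _ in range(30):
            cand = beta + step
            cand_ll = nb_loglikelihood(cand[0], cand[1], k, x, y)
            if cand_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll = beta + step, cand_ll

        # size parameter given coefficients: damped Newton on log k
        mu = np.exp(X @ beta)
        g = _nb_dll_dk(k, mu, y) * k  # d ll / d log k
        h = _nb_d2ll_dk2(k, mu, y) * k * k + g  # d2 ll / d (log k)2
        dstep = -g / h if h < 0 else np.sign(g)
        dstep = float(np.clip(dstep, -2.0, 2.0))
        for _ in range(30):
            cand_k = k * np.exp(dstep)
            cand_ll = nb_loglikelihood(beta[0], beta[1], cand_k, x, y)
            if cand_ll >= ll - 1e-12:
                break
            dstep *= 0.5
        rel = max(
            np.max(np.abs(step) / np.maximum(np.abs(beta), 1e-12)),
            abs(cand_k - k) / max(k, 1e-12),
        )
        k, ll = float(cand_k), cand_ll
        if rel < tol:
            converged = True
            break

    # observed information in (beta0, beta1, log k); the coefficient
    # block of the inverse is invariant to the k parameterization
    theta = np.array([beta[0], beta[1], np.log(k)])

    def _ll(t: np.ndarray) -> float:
        return nb_loglikelihood(t[0], t[1], np.exp(t[2]), x, y)

    H = _numeric_hessian(_ll, theta)
    try:
        cov = np.linalg.inv(-H)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
        converged = False
    slope = float(beta[1])
    irr = float(np.exp(slope))
    lo, hi = slope - _Z975 * se, slope + _Z975 * se
    p = 2 * stats.norm.sf(abs(slope) / se) if se > 0 else float("nan")
    return RegressionFit(
        method="negative_binomial",
        slope=slope,
        intercept=float(beta[0]),
        se=se,
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p_value=float(p),
        irr=irr,
        dispersion=float(k),
        n_iterations=n_iter,
        converged=bool(converged),
        n_obs=len(x),
    )


def _numeric_hessian(f, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    p = len(theta)
    H = np.empty((p, p))
    steps = h * np.maximum(np.abs(theta), 1.0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit_negative_binomial(series: TATSeries, component: str = "overall") -> RegressionFit:
    """NB2 learning-curve fit of a TAT component on case number."""
    y = series.component(component)
    return negative_binomial(series.case_index, y)
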