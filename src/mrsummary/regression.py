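"""Weighted, generalized and robust regression engines.

These are the numerical workhorses behind the IVW and MR-Egger estimators.
All engines return *raw* standard errors — square roots of the diagonal of
the unscaled inverse (weighted) normal matrix — together with the residual
standard error of the fit; the estimator layer decides whether and how to
inflate them (fixed- vs random-effects models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import solve_triangular

from .exceptions import ConvergenceError, DegenerateDesignError

__all__ = [
    "FitResult",
    "wls_no_intercept",
    "wls_with_intercept",
    "gls_fit",
    "robust_fit",
    "confidence_interval",
]


@dataclass(frozen=True)
class FitResult:
    """Coefficients and raw (unscaled) standard errors of a linear fit.

    ``intercept``/``se_intercept_raw`` are None for through-origin fits;
    ``residual_se`` is ``sqrt(weighted RSS / (J - p))`` and is ``nan`` when
    there are no residual degrees of freedom.
    """

    slope: float
    se_slope_raw: float
    residual_se: float
    intercept: float | None = None
    se_intercept_raw: float | None = None


def _check_xyw(x, y, w=None):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise DegenerateDesignError(f"x and y lengths differ: {x.shape} vs {y.shape}")
    if w is None:
        return x, y, None
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if w.shape != x.shape:
        raise DegenerateDesignError("weight length does not match data length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DegenerateDesignError("weights must be strictly positive and finite")
    return x, y, w


def wls_no_intercept(x, y, w) -> FitResult:
    """Weighted least squares through the origin.

    slope = sum(w x y) / sum(w x^2); raw SE = 1 / sqrt(sum(w x^2));
    residual_se = sqrt(sum(w (y - slope x)^2) / (J - 1)) for J >= 2.
    """
    x, y, w = _check_xyw(x, y, w)
    sxx = float(np.sum(w * x * x))
    if sxx == 0.0:
        raise DegenerateDesignError("sum(w x^2) is zero: no usable design variation")
    slope = float(np.sum(w * x * y) / sxx)
    j = x.shape[0]
    if j >= 2:
        rss = float(np.sum(w * (y - slope * x) ** 2))
        residual_se = float(np.sqrt(rss / (j - 1)))
    else:
        residual_se = float("nan")
    return FitResult(slope=slope, se_slope_raw=float(1.0 / np.sqrt(sxx)),
                     residual_se=residual_se)


def wls_with_intercept(x, y, w) -> FitResult:
    """Weighted least squares with an intercept.

    Raw SEs come from the unscaled inverse weighted normal matrix
    ``(X' W X)^{-1}``; residual_se uses J - 2 degrees of freedom (nan at
    J = 2, where the fit interpolates... residual_se is 0 there by
    convention since both residuals vanish).
    """
    x, y, w = _check_xyw(x, y, w)
    j = x.shape[0]
    if j < 2:
        raise DegenerateDesignError("at least two points are needed to fit a line")
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("x is constant: intercept and slope are collinear")
    X = np.column_stack([np.ones(j), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    cov_raw = np.linalg.inv(xtwx)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    residual_se = float(np.sqrt(rss / (j - 2))) if j > 2 else 0.0
    return FitResult(
        slope=float(coef[1]),
        se_slope_raw=float(np.sqrt(cov_raw[1, 1])),
        residual_se=residual_se,
        intercept=float(coef[0]),
        se_intercept_raw=float(np.sqrt(cov_raw[0, 0])),
    )


def gls_fit(x, y, sigma: np.ndarray, with_intercept: bool) -> FitResult:
    """Generalized weighted least squares with a full residual covariance.

    ``sigma`` is the J x J covariance of the outcome associations,
    ``Sigma_ij = byse_i byse_j rho_ij``. Coefficients are
    ``(X' Sigma^-1 X)^-1 X' Sigma^-1 y``; raw SEs are the square roots of the
    diagonal of ``(X' Sigma^-1 X)^-1``; residual_se is
    ``sqrt(r' Sigma^-1 r / (J - p))``.

    Used for the IVW method with correlated variants, and for MR-Egger by the
    same construction with an intercept column.
    """
    x, y, _ = _check_xyw(x, y)
    j = x.shape[0]
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (j, j):
        raise DegenerateDesignError(
            f"sigma must be {j}x{j}, got {sigma.shape}"
        )
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(
            "residual covariance is singular (perfectly correlated variants?); "
            "prune duplicate variants before fitting"
        ) from exc
    X = np.column_stack([np.ones(j), x]) if with_intercept else x[:, None]
    if with_intercept and np.ptp(x) == 0.0:
        raise DegenerateDesignError("x is constant: intercept and slope are collinear")
    # whiten: z = L^-1 v with sigma = L L', then OLS on whitened quantities
    Xw = solve_triangular(chol, X, lower=True)
    yw = solve_triangular(chol, y, lower=True)
    xtx = Xw.T @ Xw
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov_raw = np.linalg.inv(xtx)
    resid = yw - Xw @ coef
    p = X.shape[1]
    residual_se = (
        float(np.sqrt(float(resid @ resid) / (j - p))) if j > p else 0.0
    )
    if with_intercept:
        return FitResult(
            slope=float(coef[1]),
            se_slope_raw=float(np.sqrt(cov_raw[1, 1])),
            residual_se=residual_se,
            intercept=float(coef[0]),
            se_intercept_raw=float(np.sqrt(cov_raw[0, 0])),
        )
    return FitResult(
        slope=float(coef[0]),
        se_slope_raw=float(np.sqrt(cov_raw[0, 0])),
        residual_se=residual_se,
    )


def robust_fit(x, y, w, with_intercept: bool) -> FitResult:
    """Robust (M-type, Tukey biweight) regression on the weighted problem.

    The responses and design are pre-multiplied by sqrt(w) and fitted with
    iteratively reweighted least squares using a redescending Tukey biweight
    psi-function, so any single variant has bounded influence on the
    estimate. On outlier-free data the fit agrees with weighted least
    squares. Standard errors are the M-estimator's model-based SEs, which
    already incorporate the robust scale estimate.
    """
    x, y, w = _check_xyw(x, y, w)
    j = x.shape[0]
    if j < 3:
        raise DegenerateDesignError("robust regression needs at least 3 variants")
    if with_intercept and np.ptp(x) == 0.0:
        raise DegenerateDesignError("x is constant: intercept and slope are collinear")
    if not with_intercept and np.all(x == 0):
        raise DegenerateDesignError("x is identically zero")
    sw = np.sqrt(w)
    X = np.column_stack([sw, sw * x]) if with_intercept else (sw * x)[:, None]
    yy = sw * y
    model = sm.RLM(yy, X, M=sm.robust.norms.TukeyBiweight())
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels failure path
        raise ConvergenceError(f"robust fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError("robust fit produced non-finite coefficients")
    coef = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    p = X.shape[1]
    resid = yy - X @ coef
    residual_se = (
        float(np.sqrt(float(resid @ resid) / (j - p))) if j > p else 0.0
    )
    if with_intercept:
        return FitResult(
            slope=float(coef[1]),
            se_slope_raw=float(bse[1]),
            residual_se=residual_se,
            intercept=float(coef[0]),
            se_intercept_raw=float(bse[0]),
        )
    return FitResult(
        slope=float(coef[0]), se_slope_raw=float(bse[0]), residual_se=residual_se
    )


def confidence_interval(
    estimate: float,
    se: float,
    alpha: float = 0.05,
    distribution: str = "normal",
    df: int | None = None,
) -> tuple[float, float, float]:
    """Two-sided confidence interval and p-value for a single parameter.

    Bounds are ``estimate +/- q * se`` with ``q`` the ``1 - alpha/2``
    quantile of the chosen reference distribution; the p-value tests
    H0: parameter = 0.
    """
    if se <= 0 or not np.isfinite(se):
        raise ValueError(f"standard error must be positive and finite, got {se}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if distribution == "normal":
        q = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(estimate) / se)
    elif distribution == "t":
        if df is None or df <= 0:
            raise ValueError("t-distribution inference requires df > 0")
        q = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(estimate) / se, df)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return estimate - q * se, estimate + q * se, float(p)
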