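"""Maximum-likelihood causal estimation from summarized data.

Unlike the IVW method, which conditions on the observed variant-exposure
associations, the likelihood model treats both sets of associations as
noisy measurements of underlying parameters: per variant j,

    (bx_j, by_j) ~ bivariate Normal( (xi_j, theta * xi_j),
                                     SDs (bxse_j, byse_j), correlation psi )

where ``xi_j`` is the true variant-exposure effect and ``theta`` the causal
effect. ``psi`` captures within-variant correlation between the two
measurement errors; it is 0 in the usual two-sample setting with
non-overlapping samples and can be set for one-sample analyses.

The J + 1 free parameters (theta, xi_1..xi_J) are maximized jointly with an
analytic gradient; the standard error of theta comes from the observed
information (inverse Hessian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .data import SummaryData, validate_summary_data
from .estimators import EstimatorOptions, MREstimate
from .exceptions import ConvergenceError, DegenerateDesignError
from .regression import confidence_interval, wls_no_intercept

__all__ = ["LikelihoodModel", "loglik", "mr_maxlik"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class LikelihoodModel:
    """Parameter point of the bivariate-normal measurement model."""

    theta: float
    xi: np.ndarray
    psi: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "xi", np.atleast_1d(np.asarray(self.xi, dtype=float)))
        if not -1.0 < self.psi < 1.0:
            raise ValueError(f"psi must lie strictly in (-1, 1), got {self.psi}")
        if not np.all(np.isfinite(self.xi)):
            raise ValueError("xi must be finite")


def loglik(model: LikelihoodModel, data: SummaryData) -> float:
    """Log-likelihood: sum of per-variant bivariate normal log-densities."""
    validate_summary_data(data)
    if model.xi.shape[0] != data.n_variants:
        raise DegenerateDesignError("xi length does not match the number of variants")
    z1 = (data.bx - model.xi) / data.bxse
    z2 = (data.by - model.theta * model.xi) / data.byse
    psi = model.psi
    om = 1.0 - psi**2
    quad = (z1**2 - 2.0 * psi * z1 * z2 + z2**2) / om
    ll = -_LOG_2PI - np.log(data.bxse) - np.log(data.byse) - 0.5 * np.log(om) - 0.5 * quad
    return float(np.sum(ll))


def _negloglik_and_grad(params: np.ndarray, data: SummaryData, psi: float):
    theta, xi = params[0], params[1:]
    z1 = (data.bx - xi) / data.bxse
    z2 = (data.by - theta * xi) / data.byse
    om = 1.0 - psi**2
    quad = (z1**2 - 2.0 * psi * z1 * z2 + z2**2) / om
    nll = float(
        np.sum(_LOG_2PI + np.log(data.bxse) + np.log(data.byse)
               + 0.5 * np.log(om) + 0.5 * quad)
    )
    # d loglik / d xi_j and d loglik / d theta (closed form)
    dll_dxi = ((z1 - psi * z2) / data.bxse + theta * (z2 - psi * z1) / data.byse) / om
    dll_dtheta = float(np.sum(xi * (z2 - psi * z1) / data.byse) / om)
    grad = np.empty_like(params)
    grad[0] = -dll_dtheta
    grad[1:] = -dll_dxi
    return nll, grad


def _observed_information(params: np.ndarray, data: SummaryData, psi: float) -> np.ndarray:
    """Numeric Hessian of the negative log-likelihood via central differences
    of the analytic gradient."""
    n = params.shape[0]
    hess = np.empty((n, n))
    h = 1e-5 * np.maximum(1.0, np.abs(params))
    for i in range(n):
        up = params.copy()
        dn = params.copy()
        up[i] += h[i]
        dn[i] -= h[i]
        _, gu = _negloglik_and_grad(up, data, psi)
        _, gd = _negloglik_and_grad(dn, data, psi)
        hess[:, i] = (gu - gd) / (2.0 * h[i])
    return (hess + hess.T) / 2.0


def mr_maxlik(
    data: SummaryData,
    options: EstimatorOptions | None = None,
    psi: float = 0.0,
) -> MREstimate:
    """Maximum-likelihood causal estimate allowing for error in bx and by.

    Initialization: ``xi_j = bx_j`` and theta at the IVW estimate. The
    optimizer is L-BFGS-B with the analytic gradient, tolerance 1e-8 on the
    projected gradient norm. The standard error of theta is the square root
    of the theta-diagonal element of the inverse observed information.

    With a single variant the likelihood is exactly identified and the
    estimate is the Wald ratio ``by/bx``; as ``bxse -> 0`` the estimate
    converges to the IVW estimate.
    """
    options = options or EstimatorOptions()
    validate_summary_data(data)
    if not -1.0 < psi < 1.0:
        raise ValueError(f"psi must lie strictly in (-1, 1), got {psi}")
    j = data.n_variants
    if np.all(np.abs(data.bx) < 1e-12):
        raise DegenerateDesignError(
            "all exposure associations are (near) zero: theta is unidentifiable"
        )
    theta0 = wls_no_intercept(data.bx, data.by, 1.0 / data.byse**2).slope
    x0 = np.concatenate([[theta0], data.bx])
    res = optimize.minimize(
        _negloglik_and_grad,
        x0,
        args=(data, psi),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "gtol": 1e-8, "ftol": 1e-14},
    )
    params = res.x
    # Newton polish: the likelihood is sharply curved when SEs are small and
    # L-BFGS-B can stop with a tiny-but-nonzero gradient; a few information-
    # matrix steps drive the Newton decrement to machine level.
    converged = False
    info = _observed_information(params, data, psi)
    for _ in range(25):
        nll, grad = _negloglik_and_grad(params, data, psi)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        if np.max(np.abs(step)) < 1e-10 * max(1.0, np.max(np.abs(params))):
            converged = True
            break
        new = params - step
        if _negloglik_and_grad(new, data, psi)[0] > nll + 1e-9 * abs(nll):
            break  # step does not improve: stay at the current iterate
        params = new
        info = _observed_information(params, data, psi)
    if not (converged or res.success):
        _, grad = _negloglik_and_grad(params, data, psi)
        raise ConvergenceError(
            f"likelihood maximization did not converge: {res.message} "
            f"(|grad|_inf = {np.linalg.norm(grad, ord=np.inf):.3g})"
        )
    theta_hat = float(params[0])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("observed information is singular") from exc
    var_theta = float(cov[0, 0])
    if var_theta <= 0:
        raise ConvergenceError(
            "observed information is not positive definite at the optimum"
        )
    se = float(np.sqrt(var_theta))
    df = j - 1 if options.distribution == "t" else None
    if options.distribution == "t" and (df is None or df <= 0):
        raise ValueError("t-based inference needs J >= 2 for the likelihood method")
    lo, hi, p = confidence_interval(
        theta_hat, se, alpha=options.alpha,
        distribution=options.distribution, df=df,
    )
    return MREstimate(
        method="Maximum likelihood",
        estimate=theta_hat,
        std_error=se,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        n_variants=j,
        options=options,
        diagnostics={
            "converged": bool(converged or res.success),
            "n_iterations": int(res.nit),
            "final_loglik": -_negloglik_and_grad(params, data, psi)[0],
            "initial_loglik": float(
                loglik(LikelihoodModel(theta=theta0, xi=data.bx.copy(), psi=psi), data)
            ),
            "psi": psi,
        },
    )
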