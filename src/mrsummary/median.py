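"""Simple, weighted and penalized-weighted median causal estimators.

The median-based method takes the per-variant ratio estimates
``theta_j = by_j / bx_j`` and returns their (weighted) median. It is
consistent when variants carrying at least half of the weight are valid
instruments, even if the rest are pleiotropic — a strictly weaker condition
than the IVW method requires. Standard errors come from a seeded parametric
bootstrap on the summary statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import SummaryData, validate_summary_data
from .exceptions import DegenerateDesignError, InsufficientVariantsError, MRError
from .regression import confidence_interval
from .weights import PENALTY_MULTIPLIER
from .estimators import EstimatorOptions, MREstimate

__all__ = ["BootstrapConfig", "weighted_percentile", "bootstrap_se", "mr_median"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Parametric bootstrap settings for the median standard error."""

    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def weighted_percentile(values, weights, p: float) -> float:
    """Interpolated weighted percentile with cumulative-midpoint positions.

    Sort the values ascending, carrying their weights; assign each order
    statistic the position ``s_k = (sum_{i<=k} w_i - w_k/2) / sum(w)`` and
    linearly interpolate values against positions at ``p``. Queries outside
    ``[s_1, s_J]`` clamp to the extreme values. With equal weights and
    ``p = 0.5`` this reduces to the ordinary sample median.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    weights = np.atleast_1d(np.asarray(weights, dtype=float))
    if values.shape != weights.shape:
        raise DegenerateDesignError("values and weights must have equal length")
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise DegenerateDesignError("weights must be nonnegative and finite")
    total = float(weights.sum())
    if total <= 0:
        raise DegenerateDesignError("weights must not all be zero")
    if not 0 <= p <= 1:
        raise ValueError(f"percentile fraction must lie in [0, 1], got {p}")
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    s = (np.cumsum(w) - 0.5 * w) / total
    return float(np.interp(p, s, v))


def _ratio_weights(data: SummaryData, variant: str):
    """Per-variant ratios and (unnormalized) median weights, dropping bx = 0."""
    usable = data.bx != 0
    if not usable.any():
        raise DegenerateDesignError(
            "all variant-exposure associations are zero: ratios undefined"
        )
    if not usable.all():
        labels = [lab for lab, u in zip(data.labels(), usable) if not u]
        warnings.warn(
            f"dropping {len(labels)} variant(s) with bx = 0 from the median "
            f"method (ratio undefined): {', '.join(labels)}",
            stacklevel=3,
        )
    bx, bxse = data.bx[usable], data.bxse[usable]
    by, byse = data.by[usable], data.byse[usable]
    theta = by / bx
    if variant == "simple":
        w = np.ones_like(theta)
    else:
        # first-order inverse variance of the ratio estimate
        w = bx**2 / byse**2
    return theta, w, bx, bxse, by, byse


def _penalized_median_point(data: SummaryData) -> float:
    """Weighted median with chi-square penalization of heterogeneous variants."""
    from scipy import stats

    theta, w, bx, bxse, by, byse = _ratio_weights(data, "weighted")
    ref = weighted_percentile(theta, w, 0.5)
    # w = bx^2/byse^2 is the first-order inverse variance of theta_j, so
    # q_j = w_j (theta_j - ref)^2 is the chi-square(1) heterogeneity score
    q = w * (theta - ref) ** 2
    factor = np.minimum(1.0, PENALTY_MULTIPLIER * stats.chi2.sf(q, 1))
    w_star = w * factor
    if w_star.sum() <= 0:  # pragma: no cover - pathological
        w_star = w
    return weighted_percentile(theta, w_star, 0.5)


def bootstrap_se(
    data: SummaryData,
    estimator: Callable[[SummaryData], float],
    config: BootstrapConfig,
) -> float:
    """Parametric-bootstrap standard error of a summary-data estimator.

    Each iteration draws ``bx* ~ N(bx, bxse^2)`` and ``by* ~ N(by, byse^2)``
    independently per variant, re-applies the estimator, and the sample
    standard deviation of the replicates is returned. Deterministic given
    ``config.seed``. Iterations in which the estimator fails are dropped and
    counted; more than 10% failures raises.
    """
    rng = np.random.default_rng(config.seed)
    estimates = []
    failures = 0
    for _ in range(config.n_iterations):
        bx = rng.normal(data.bx, data.bxse)
        by = rng.normal(data.by, data.byse)
        star = SummaryData(
            bx=bx, bxse=data.bxse, by=by, byse=data.byse,
            variant_ids=data.variant_ids,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimates.append(estimator(star))
        except MRError:
            failures += 1
    if failures > 0.1 * config.n_iterations:
        raise DegenerateDesignError(
            f"bootstrap failed in {failures}/{config.n_iterations} iterations"
        )
    est = np.asarray(estimates)
    if len(est) < 2:
        return 0.0
    return float(np.std(est, ddof=1))


def mr_median(
    data: SummaryData,
    variant: str = "weighted",
    options: EstimatorOptions | None = None,
    bootstrap: BootstrapConfig | None = None,
) -> MREstimate:
    """Median-based causal estimate (simple, weighted or penalized weights).

    ``variant="simple"`` takes the plain median of the per-variant ratios;
    ``"weighted"`` weights each ratio by its first-order inverse variance
    ``bx^2/byse^2``; ``"penalized"`` additionally down-weights variants whose
    ratios are heterogeneous relative to the weighted-median reference.
    Variants with ``bx = 0`` are dropped with a warning (their ratio is
    undefined). The standard error is a seeded parametric bootstrap.
    """
    if variant not in ("simple", "weighted", "penalized"):
        raise ValueError(f"unknown median variant {variant!r}")
    options = options or EstimatorOptions()
    bootstrap = bootstrap or BootstrapConfig()
    validate_summary_data(data)
    j_usable = int(np.count_nonzero(data.bx != 0))
    if j_usable < 2:
        raise InsufficientVariantsError(
            "median methods need at least 2 variants with nonzero bx"
        )
    if j_usable < 10:
        warnings.warn(
            f"median method with only {j_usable} variants: the estimator is "
            "intended for analyses with many instruments",
            stacklevel=2,
        )

    if variant == "penalized":
        point_fn = _penalized_median_point
    else:
        def point_fn(d, _v=variant):
            theta, w, *_ = _ratio_weights(d, _v)
            return weighted_percentile(theta, w, 0.5)

    estimate = point_fn(data)
    se = bootstrap_se(data, point_fn, bootstrap)
    if se == 0.0:
        # degenerate (zero sampling noise); report a point mass
        lo = hi = estimate
        p = 0.0 if estimate != 0 else 1.0
    else:
        df = j_usable - 1 if options.distribution == "t" else None
        lo, hi, p = confidence_interval(
            estimate, se, alpha=options.alpha,
            distribution=options.distribution, df=df,
        )
    labels = {
        "simple": "Simple median",
        "weighted": "Weighted median",
        "penalized": "Penalized weighted median",
    }
    return MREstimate(
        method=labels[variant],
        estimate=estimate,
        std_error=se,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        n_variants=j_usable,
        options=options,
        diagnostics={"bootstrap_iterations": bootstrap.n_iterations},
    )
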