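"""IVW and MR-Egger causal estimators.

The inverse-variance weighted (IVW) method regresses the variant-outcome
associations on the variant-exposure associations through the origin with
weights ``1/byse^2``; it is the summarized-data analogue of two-stage least
squares and is consistent when every variant is a valid instrument.

MR-Egger fits the same weighted regression with an unconstrained intercept
after orienting every variant to its exposure-increasing allele. The
intercept estimates the average directional pleiotropic effect of a variant;
the slope remains a consistent causal estimate under the weaker InSIDE
assumption (instrument strength independent of direct effects).

Both estimators support fixed- or multiplicative random-effects standard
errors, robust regression, weight penalization, t-based inference, a
configurable confidence level, and generalized weighted regression for
correlated variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import SummaryData, orient_to_exposure_increasing, validate_summary_data
from .exceptions import DataStructureError, InsufficientVariantsError
from .regression import (
    FitResult,
    confidence_interval,
    gls_fit,
    robust_fit,
    wls_no_intercept,
    wls_with_intercept,
)
from .weights import (
    HeterogeneityReport,
    cochran_q,
    first_order_weights,
    i_squared_gx,
    penalized_weights,
)

__all__ = ["EstimatorOptions", "MREstimate", "ParameterEstimate", "mr_ivw", "mr_egger"]


@dataclass(frozen=True)
class EstimatorOptions:
    """Analysis options shared by the regression-based estimators.

    effects_model
        ``"random"`` (default) inflates raw standard errors by
        ``max(1, residual_se)``; ``"fixed"`` reports the raw SE regardless of
        heterogeneity. Point estimates are identical under both.
    robust
        Use robust (Tukey biweight) regression instead of least squares.
    penalized
        Penalize the weights of variants with heterogeneous causal estimates.
    distribution
        ``"normal"`` or ``"t"`` reference distribution for CIs and p-values.
    alpha
        Two-sided CI tail mass; 0.05 gives a 95% confidence interval.
    correlated
        Account for between-variant correlation via generalized weighted
        regression; requires ``data.correlation``.
    """

    effects_model: str = "random"
    robust: bool = False
    penalized: bool = False
    distribution: str = "normal"
    alpha: float = 0.05
    correlated: bool = False

    def __post_init__(self):
        if self.effects_model not in ("fixed", "random"):
            raise ValueError(f"effects_model must be fixed|random, got {self.effects_model!r}")
        if self.distribution not in ("normal", "t"):
            raise ValueError(f"distribution must be normal|t, got {self.distribution!r}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.correlated and self.robust:
            raise ValueError(
                "robust regression with correlated variants is not supported: "
                "no established construction combines the two"
            )
        if self.correlated and self.penalized:
            raise ValueError(
                "weight penalization is defined for uncorrelated variants only"
            )


@dataclass(frozen=True)
class ParameterEstimate:
    """One fitted parameter with its inference summary."""

    estimate: float
    std_error: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate with its uncertainty and diagnostics.

    ``estimate`` is in outcome units per exposure unit (a log odds ratio per
    exposure unit when the outcome associations are log odds ratios).
    ``intercept`` is populated by MR-Egger only and estimates the average
    pleiotropic effect per variant. ``heterogeneity`` carries Cochran's Q and
    the residual standard error of the weighted fit; ``i_squared_gx`` (Egger
    only) quantifies susceptibility to weak-instrument dilution.
    """

    method: str
    estimate: float
    std_error: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_variants: int
    options: EstimatorOptions
    intercept: ParameterEstimate | None = None
    heterogeneity: HeterogeneityReport | None = None
    i_squared_gx: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __str__(self) -> str:
        level = 100 * (1 - self.options.alpha)
        lines = [
            f"{self.method} ({self.n_variants} variants)",
            f"  Estimate : {self.estimate:10.4g}",
            f"  Std Error: {self.std_error:10.4g}",
            f"  {level:.0f}% CI  : ({self.ci_lower:.4g}, {self.ci_upper:.4g})",
            f"  p-value  : {self.p_value:.4g}",
        ]
        if self.intercept is not None:
            ic = self.intercept
            lines += [
                "  Intercept (average pleiotropic effect):",
                f"    {ic.estimate:.4g} (SE {ic.std_error:.4g}), "
                f"{level:.0f}% CI ({ic.ci_lower:.4g}, {ic.ci_upper:.4g}), "
                f"p = {ic.p_value:.4g}",
            ]
        if self.heterogeneity is not None and self.heterogeneity.p_value is not None:
            h = self.heterogeneity
            lines.append(
                f"  Heterogeneity: Q = {h.Q:.4g} on {h.df} df "
                f"(p = {h.p_value:.4g}), residual SE = {h.residual_se:.4g}"
            )
        if self.i_squared_gx is not None:
            lines.append(f"  I^2_GX: {self.i_squared_gx:.3f}")
        return "\n".join(lines)


def _inflation(options: EstimatorOptions, residual_se: float) -> float:
    """Multiplicative SE inflation: max(1, residual SE) under random effects."""
    if options.effects_model == "random" and np.isfinite(residual_se):
        return max(1.0, residual_se)
    return 1.0


def _sigma_matrix(data: SummaryData) -> np.ndarray:
    rho = data.correlation.values
    return np.outer(data.byse, data.byse) * rho


def mr_ivw(data: SummaryData, options: EstimatorOptions | None = None) -> MREstimate:
    """Inverse-variance weighted causal estimate.

    With a single variant this is the Wald ratio ``by/bx`` with standard
    error ``byse/|bx|``. With J >= 2 variants the estimate is the weighted
    through-origin regression slope of ``by`` on ``bx``; a Cochran Q
    heterogeneity report is attached. Inference uses a normal reference by
    default, or a t with J - 1 degrees of freedom.
    """
    options = options or EstimatorOptions()
    validate_summary_data(data)
    j = data.n_variants
    diagnostics: dict = {}

    if options.correlated:
        if data.correlation is None:
            raise DataStructureError(
                "options.correlated requires data.correlation to be present"
            )
        fit = gls_fit(data.bx, data.by, _sigma_matrix(data), with_intercept=False)
        wq = None
    else:
        w = first_order_weights(data)
        if options.penalized:
            ref = wls_no_intercept(data.bx, data.by, w.w).slope
            w = penalized_weights(data, ref, w)
            diagnostics["penalization_reference"] = ref
        if options.robust:
            fit = robust_fit(data.bx, data.by, w.w, with_intercept=False)
        else:
            fit = wls_no_intercept(data.bx, data.by, w.w)
        wq = w

    se = fit.se_slope_raw * _inflation(options, fit.residual_se)
    if j == 1:
        # single-variant Wald ratio: residual df = 0, no heterogeneity
        se = fit.se_slope_raw
        het = None
    elif wq is not None:
        het = cochran_q(data, fit.slope, wq, n_params=1)
    else:
        # correlated case: Q from the whitened residual sum of squares
        q = fit.residual_se**2 * (j - 1)
        het = HeterogeneityReport(
            Q=q, df=j - 1, p_value=float(stats.chi2.sf(q, j - 1)),
            residual_se=fit.residual_se,
        )
    df = j - 1 if options.distribution == "t" else None
    if options.distribution == "t" and j < 2:
        raise InsufficientVariantsError("t-based inference needs J >= 2 for the IVW method")
    lo, hi, p = confidence_interval(
        fit.slope, se, alpha=options.alpha, distribution=options.distribution, df=df
    )
    label = "IVW"
    if options.penalized and options.robust:
        label = "Penalized robust IVW"
    elif options.penalized:
        label = "Penalized IVW"
    elif options.robust:
        label = "Robust IVW"
    elif options.correlated:
        label = "IVW (correlated)"
    return MREstimate(
        method=label,
        estimate=fit.slope,
        std_error=se,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        n_variants=j,
        options=options,
        heterogeneity=het,
        diagnostics=diagnostics,
    )


def mr_egger(data: SummaryData, options: EstimatorOptions | None = None) -> MREstimate:
    """MR-Egger regression: causal slope plus average-pleiotropy intercept.

    All variants are first oriented to the exposure-increasing allele (this
    re-orientation is integral to the method and not user-disableable: the
    intercept is only interpretable with a common orientation). Requires
    J >= 3 variants. Random-effects inflation ``max(1, residual_se)`` is
    applied to both parameters; t-based inference uses J - 2 degrees of
    freedom. The I^2_GX weak-instrument statistic of the oriented exposure
    associations is attached.
    """
    options = options or EstimatorOptions()
    validate_summary_data(data)
    j = data.n_variants
    if j < 3:
        raise InsufficientVariantsError(
            f"MR-Egger requires at least 3 variants, got {j}"
        )
    oriented = orient_to_exposure_increasing(data)
    diagnostics: dict = {}

    if options.correlated:
        if oriented.correlation is None:
            raise DataStructureError(
                "options.correlated requires data.correlation to be present"
            )
        fit = gls_fit(
            oriented.bx, oriented.by, _sigma_matrix(oriented), with_intercept=True
        )
        wq = None
    else:
        w = first_order_weights(oriented)
        if options.penalized:
            ref = wls_no_intercept(oriented.bx, oriented.by, w.w).slope
            w = penalized_weights(oriented, ref, w)
            diagnostics["penalization_reference"] = ref
        if options.robust:
            fit = robust_fit(oriented.bx, oriented.by, w.w, with_intercept=True)
        else:
            fit = wls_with_intercept(oriented.bx, oriented.by, w.w)
        wq = w

    infl = _inflation(options, fit.residual_se)
    se_slope = fit.se_slope_raw * infl
    se_int = fit.se_intercept_raw * infl
    df = j - 2 if options.distribution == "t" else None
    lo, hi, p = confidence_interval(
        fit.slope, se_slope, alpha=options.alpha,
        distribution=options.distribution, df=df,
    )
    ilo, ihi, ip = confidence_interval(
        fit.intercept, se_int, alpha=options.alpha,
        distribution=options.distribution, df=df,
    )
    if wq is not None:
        het = cochran_q(oriented, fit.slope, wq, n_params=2, intercept=fit.intercept)
    else:
        q = fit.residual_se**2 * (j - 2)
        het = HeterogeneityReport(
            Q=q, df=j - 2, p_value=float(stats.chi2.sf(q, j - 2)),
            residual_se=fit.residual_se,
        )
    label = "MR-Egger"
    if options.penalized and options.robust:
        label = "Penalized robust MR-Egger"
    elif options.penalized:
        label = "Penalized MR-Egger"
    elif options.robust:
        label = "Robust MR-Egger"
    elif options.correlated:
        label = "MR-Egger (correlated)"
    return MREstimate(
        method=label,
        estimate=fit.slope,
        std_error=se_slope,
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        n_variants=j,
        options=options,
        intercept=ParameterEstimate(
            estimate=fit.intercept, std_error=se_int,
            ci_lower=ilo, ci_upper=ihi, p_value=ip,
        ),
        heterogeneity=het,
        i_squared_gx=i_squared_gx(oriented),
        diagnostics=diagnostics,
    )
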