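"""Inverse-variance weights, heterogeneity statistics and penalization.

Service layer shared by every estimator: first-order inverse-variance
weights ``w_j = 1/byse_j^2``, the Cochran heterogeneity statistic of the
per-variant causal estimates, the chi-square penalization of heterogeneous
variants, and the I^2_GX weak-instrument statistic reported alongside
MR-Egger results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data import SummaryData
from .exceptions import DegenerateDesignError

__all__ = [
    "WeightVector",
    "HeterogeneityReport",
    "first_order_weights",
    "cochran_q",
    "penalized_weights",
    "i_squared_gx",
    "PENALTY_MULTIPLIER",
]

#: multiplier applied to the chi-square(1) upper tail probability when
#: penalizing heterogeneous variants: w*_j = w_j * min(1, 20 p_j). With this
#: constant the penalty factor is exactly 1 at the upper-5% quantile of
#: chi-square(1) and shrinks smoothly beyond it.
PENALTY_MULTIPLIER = 20.0


@dataclass(frozen=True)
class WeightVector:
    """Per-variant nonnegative regression weights."""

    w: np.ndarray
    scheme: str = "first_order"
    penalized: bool = False

    def __post_init__(self):
        w = np.atleast_1d(np.asarray(self.w, dtype=float))
        object.__setattr__(self, "w", w)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise DegenerateDesignError("weights must be finite and nonnegative")
        if not np.any(w > 0):
            raise DegenerateDesignError("at least one weight must be positive")

    def __len__(self) -> int:
        return self.w.shape[0]


@dataclass(frozen=True)
class HeterogeneityReport:
    """Cochran Q test of the dispersion of per-variant causal estimates.

    ``residual_se`` is the residual standard error of the weighted fit,
    ``sqrt(Q/df)``; values well above 1 indicate that the variant-specific
    estimates disagree more than their sampling error explains, suggesting
    pleiotropy for one or more variants. ``p_value`` is None when df <= 0.
    """

    Q: float
    df: int
    p_value: float | None
    residual_se: float


def first_order_weights(data: SummaryData) -> WeightVector:
    """First-order inverse-variance weights ``w_j = 1 / byse_j^2``.

    Uncertainty in the variant-exposure associations is ignored, as is
    standard for the IVW and MR-Egger methods.
    """
    return WeightVector(w=1.0 / data.byse**2)


def cochran_q(
    data: SummaryData,
    theta: float,
    w: WeightVector | np.ndarray,
    n_params: int = 1,
    intercept: float = 0.0,
) -> HeterogeneityReport:
    """Cochran heterogeneity statistic ``Q = sum_j w_j (by_j - a - theta bx_j)^2``.

    ``n_params`` is the number of fitted regression parameters: 1 for IVW
    (``intercept`` fixed at 0), 2 for MR-Egger (pass the fitted intercept).
    Degrees of freedom are ``J - n_params``; the p-value is the upper tail of
    chi-square(df) at Q. With df <= 0 the p-value is undefined (None).
    """
    wv = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    resid = data.by - intercept - theta * data.bx
    q = float(np.sum(wv * resid**2))
    df = data.n_variants - n_params
    if df <= 0:
        return HeterogeneityReport(Q=q, df=df, p_value=None, residual_se=0.0)
    return HeterogeneityReport(
        Q=q,
        df=df,
        p_value=float(stats.chi2.sf(q, df)),
        residual_se=float(np.sqrt(q / df)),
    )


def penalized_weights(
    data: SummaryData,
    theta_ref: float,
    w: WeightVector,
    multiplier: float = PENALTY_MULTIPLIER,
) -> WeightVector:
    """Down-weight variants whose causal estimates are heterogeneous.

    Each variant's heterogeneity contribution at the reference estimate,
    ``q_j = w_j (by_j - theta_ref bx_j)^2``, is referred to a chi-square(1)
    distribution; the weight is multiplied by ``min(1, multiplier * p_j)``
    where ``p_j`` is the upper tail probability. Homogeneous variants
    (``q_j`` below the upper-``1/multiplier`` quantile) keep their weight;
    outlying variants are shrunk smoothly toward zero. The reference estimate
    is conventionally the unpenalized IVW estimate, one pass only.
    """
    q = w.w * (data.by - theta_ref * data.bx) ** 2
    p = stats.chi2.sf(q, 1)
    factor = np.minimum(1.0, multiplier * p)
    return replace(w, w=w.w * factor, penalized=True)


def i_squared_gx(data: SummaryData) -> float:
    """I^2_GX statistic: relative dispersion of the exposure associations.

    ``Q_GX = sum_j (bx_j - bbar)^2 / bxse_j^2`` with ``bbar`` the
    inverse-variance weighted mean of ``bx``;
    ``I^2_GX = max(0, (Q_GX - (J-1)) / Q_GX)``.

    Values near 1 mean the spread of the exposure associations dwarfs their
    measurement error, so regression-dilution (weak instrument) bias in the
    MR-Egger slope is small; low values flag substantial attenuation. Compute
    on data already oriented to the exposure-increasing allele, as MR-Egger
    does internally. Returns 0 (with a warning) for degenerate data with no
    dispersion at all.
    """
    v = 1.0 / data.bxse**2
    bbar = float(np.sum(v * data.bx) / np.sum(v))
    q_gx = float(np.sum(v * (data.bx - bbar) ** 2))
    # scale-relative zero test: exact-equal bx leaves rounding residue only
    if q_gx <= 1e-12 * max(float(np.sum(v * data.bx**2)), 1e-300):
        warnings.warn(
            "I^2_GX undefined: exposure associations have no dispersion; returning 0",
            stacklevel=2,
        )
        return 0.0
    return max(0.0, (q_gx - (data.n_variants - 1)) / q_gx)
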