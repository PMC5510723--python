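"""Synthetic data generation with known ground truth, plus a 2SLS oracle.

Two generators are provided:

* :func:`simulate_individual_data` draws individual-level data from a
  standard instrumental-variable model — binomial genotypes, a shared normal
  confounder, per-variant direct (pleiotropic) outcome effects — and
  :func:`summarize_individual_data` reduces them to per-variant regression
  summaries, emulating how GWAS consortia produce summarized association
  data. :func:`simulate_two_sample` chains them on two independent cohorts,
  the usual two-sample design.
* :func:`simulate_summary_data` draws summary statistics directly from their
  sampling model (``bx_j ~ N(gamma_j, bxse^2)``,
  ``by_j ~ N(theta*gamma_j + alpha_j, byse^2)``), which is cheap enough for
  coverage and recovery studies with thousands of replicates.

:func:`two_stage_least_squares` is the classical individual-level IV
estimator, used as an independent oracle: IVW on the per-variant summaries
of a cohort agrees with 2SLS on the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import SummaryData
from .exceptions import DegenerateDesignError

__all__ = [
    "SimulationConfig",
    "IndividualData",
    "simulate_individual_data",
    "summarize_individual_data",
    "simulate_two_sample",
    "simulate_correlated_genotypes",
    "two_stage_least_squares",
    "simulate_summary_data",
    "SummaryTruth",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generating model for the instrumental-variable simulations.

    The exposure is
    ``x_i = sum_j gamma_j g_ij + confounder_effect_x u_i + eps_x`` and the
    outcome
    ``y_i = theta x_i + sum_j alpha_j g_ij + confounder_effect_y u_i + eps_y``
    with ``g_ij ~ Binomial(2, maf_j)``, ``u_i ~ N(0,1)`` and independent
    normal noise. ``alpha`` encodes pleiotropy: with ``pleiotropy_mode``
    "none" all alpha are zero; "balanced" draws them zero-mean; "directional"
    draws them with positive mean, independent of gamma (so the InSIDE
    assumption holds); "inside_violating" makes them correlated with gamma.
    Explicit ``alpha`` overrides the mode.

    Defaults describe a well-powered two-sample study: 10 000 individuals,
    10 independent variants of frequency 0.3 each explaining about 0.9% of
    exposure variance (per-variant F roughly 90), moderate confounding, and
    a causal effect of 0.2.
    """

    n_individuals: int = 10_000
    n_variants: int = 10
    maf: float | np.ndarray = 0.3
    gamma: float | np.ndarray = 0.15
    theta: float = 0.2
    alpha: Optional[np.ndarray] = None
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.05
    pleiotropy_sd: float = 0.02
    confounder_effect_x: float = 0.5
    confounder_effect_y: float = 0.5
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        maf = np.broadcast_to(np.asarray(self.maf, dtype=float), (self.n_variants,))
        if np.any((maf <= 0) | (maf > 0.5)):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.pleiotropy_mode not in (
            "none", "balanced", "directional", "inside_violating"
        ):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")

    def maf_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.maf, dtype=float), (self.n_variants,)
        ).copy()

    def gamma_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.gamma, dtype=float), (self.n_variants,)
        ).copy()

    def draw_alpha(self, rng: np.random.Generator) -> np.ndarray:
        """Direct (pleiotropic) variant-outcome effects under the chosen mode."""
        if self.alpha is not None:
            a = np.broadcast_to(
                np.asarray(self.alpha, dtype=float), (self.n_variants,)
            ).copy()
            return a
        j = self.n_variants
        if self.pleiotropy_mode == "none":
            return np.zeros(j)
        if self.pleiotropy_mode == "balanced":
            return rng.normal(0.0, self.pleiotropy_sd, j)
        if self.pleiotropy_mode == "directional":
            return rng.normal(self.pleiotropy_mean, self.pleiotropy_sd, j)
        # inside_violating: direct effects proportional to instrument strength
        gamma = self.gamma_vector()
        return self.pleiotropy_mean * gamma / np.mean(np.abs(gamma)) + rng.normal(
            0.0, self.pleiotropy_sd, j
        )


@dataclass(frozen=True)
class IndividualData:
    """One simulated cohort: genotypes, exposure, outcome and the truth."""

    genotypes: np.ndarray  # n x J dosage matrix (0/1/2)
    x: np.ndarray
    y: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    theta: float


def simulate_individual_data(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> IndividualData:
    """Draw one cohort from the instrumental-variable generating model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, j = config.n_individuals, config.n_variants
    maf = config.maf_vector()
    gamma = config.gamma_vector()
    alpha = config.draw_alpha(rng)
    g = rng.binomial(2, maf, size=(n, j)).astype(float)
    u = rng.normal(0.0, 1.0, n)
    x = (
        g @ gamma
        + config.confounder_effect_x * u
        + rng.normal(0.0, config.noise_sd_x, n)
    )
    y = (
        config.theta * x
        + g @ alpha
        + config.confounder_effect_y * u
        + rng.normal(0.0, config.noise_sd_y, n)
    )
    return IndividualData(genotypes=g, x=x, y=y, gamma=gamma, alpha=alpha,
                          theta=config.theta)


def _simple_regression(g: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Slope and SE of the simple linear regression of z on g."""
    n = g.shape[0]
    gc = g - g.mean()
    sxx = float(gc @ gc)
    slope = float(gc @ z / sxx)
    resid = z - z.mean() - slope * gc
    sigma2 = float(resid @ resid) / (n - 2)
    return slope, float(np.sqrt(sigma2 / sxx))


def summarize_individual_data(
    genotypes: np.ndarray, x: np.ndarray, y: np.ndarray
) -> SummaryData:
    """Per-variant regression summaries of a cohort.

    Each variant is regressed marginally: x on g_j gives (bx_j, bxse_j) and
    y on g_j gives (by_j, byse_j) — the way GWAS summary statistics are
    produced. Monomorphic variants (zero genotype variance) are excluded
    with a warning.
    """
    import warnings

    g = np.asarray(genotypes, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.ndim != 2 or g.shape[0] != x.shape[0] or x.shape != y.shape:
        raise DegenerateDesignError("genotypes, x and y have inconsistent shapes")
    keep = np.ptp(g, axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} monomorphic variant(s) "
            "with zero genotype variance",
            stacklevel=2,
        )
    if not keep.any():
        raise DegenerateDesignError("all variants are monomorphic")
    cols = np.flatnonzero(keep)
    bx = np.empty(cols.size)
    bxse = np.empty(cols.size)
    by = np.empty(cols.size)
    byse = np.empty(cols.size)
    for k, jcol in enumerate(cols):
        bx[k], bxse[k] = _simple_regression(g[:, jcol], x)
        by[k], byse[k] = _simple_regression(g[:, jcol], y)
    ids = tuple(f"snp_{jcol + 1}" for jcol in cols)
    return SummaryData(bx=bx, bxse=bxse, by=by, byse=byse, variant_ids=ids)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[SummaryData, IndividualData, IndividualData]:
    """Two-sample summary statistics from two independent simulated cohorts.

    The exposure associations come from one cohort and the outcome
    associations from a second cohort drawn with the same generating
    parameters (same gamma and alpha), matching the non-overlapping-samples
    setting summarized-data MR methods target.
    """
    rng = np.random.default_rng(config.seed)
    alpha = config.draw_alpha(rng)
    fixed = SimulationConfig(
        **{**config.__dict__, "alpha": alpha}
    )
    cohort_x = simulate_individual_data(fixed, rng)
    cohort_y = simulate_individual_data(fixed, rng)
    sx = summarize_individual_data(cohort_x.genotypes, cohort_x.x, cohort_x.y)
    sy = summarize_individual_data(cohort_y.genotypes, cohort_y.x, cohort_y.y)
    if sx.n_variants != sy.n_variants or sx.variant_ids != sy.variant_ids:
        shared = [v for v in sx.variant_ids if v in set(sy.variant_ids)]
        ix = [sx.variant_ids.index(v) for v in shared]
        iy = [sy.variant_ids.index(v) for v in shared]
        data = SummaryData(
            bx=sx.bx[ix], bxse=sx.bxse[ix], by=sy.by[iy], byse=sy.byse[iy],
            variant_ids=tuple(shared),
        )
    else:
        data = SummaryData(
            bx=sx.bx, bxse=sx.bxse, by=sy.by, byse=sy.byse,
            variant_ids=sx.variant_ids,
        )
    return data, cohort_x, cohort_y


def simulate_correlated_genotypes(
    n: int,
    maf: np.ndarray,
    rho: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotypes with between-variant LD via a Gaussian-copula threshold.

    Each of the two haplotypes per individual is a latent multivariate
    normal draw with correlation ``rho``, thresholded at the allele-frequency
    quantile; the dosage is the sum of the two haplotypes. The realized
    genotype correlation approximates (is attenuated relative to) the latent
    ``rho``; it is adequate for exercising the correlated-variant estimators,
    not for emulating real human LD structure.
    """
    maf = np.asarray(maf, dtype=float)
    j = maf.shape[0]
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (j, j):
        raise DegenerateDesignError(f"rho must be {j}x{j}, got {rho.shape}")
    from scipy import stats as _st

    thresh = _st.norm.ppf(maf)
    chol = np.linalg.cholesky(rho + 1e-10 * np.eye(j))
    hap1 = (rng.standard_normal((n, j)) @ chol.T) < thresh
    hap2 = (rng.standard_normal((n, j)) @ chol.T) < thresh
    return (hap1.astype(float) + hap2.astype(float))


def two_stage_least_squares(
    genotypes: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Classical 2SLS causal estimate and conventional SE.

    Stage 1 regresses the exposure on all genotypes jointly (with an
    intercept); stage 2 regresses the outcome on the fitted exposure. The
    standard error uses the conventional 2SLS residual variance, computed
    from the *observed* exposure at the stage-2 coefficients.
    """
    g = np.asarray(genotypes, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, j = g.shape
    if n <= j + 1:
        raise DegenerateDesignError(
            f"2SLS needs n > J + 1 (got n = {n}, J = {j})"
        )
    Z = np.column_stack([np.ones(n), g])
    beta1, *_ = np.linalg.lstsq(Z, x, rcond=None)
    xhat = Z @ beta1
    if np.ptp(xhat) == 0:
        raise DegenerateDesignError("fitted exposure is constant: weak/collinear instruments")
    rank = np.linalg.matrix_rank(Z)
    if rank < j + 1:
        raise DegenerateDesignError("collinear genotypes: instrument matrix is rank deficient")
    X2 = np.column_stack([np.ones(n), xhat])
    beta2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    # conventional 2SLS variance: residuals evaluated at the observed exposure
    resid = y - beta2[0] - beta2[1] * x
    sigma2 = float(resid @ resid) / (n - 2)
    xtx_inv = np.linalg.inv(X2.T @ X2)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    return float(beta2[1]), se


@dataclass(frozen=True)
class SummaryTruth:
    """SummaryData drawn directly from its sampling model, plus the truth."""

    data: SummaryData
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray


def simulate_summary_data(
    config: SimulationConfig,
    bxse: float | np.ndarray = 0.02,
    byse: float | np.ndarray = 0.05,
    rng: np.random.Generator | None = None,
) -> SummaryTruth:
    """Draw summary statistics directly from their sampling distribution.

    ``bx_j ~ N(gamma_j, bxse_j^2)`` and
    ``by_j ~ N(theta gamma_j + alpha_j, byse_j^2)``, independent across
    variants and between the two sides (two-sample setting). Orders of
    magnitude faster than the individual-level route; used for coverage and
    recovery studies. With all SEs zero the ratios satisfy
    ``by_j/bx_j = theta + alpha_j/gamma_j`` exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    j = config.n_variants
    gamma = config.gamma_vector()
    alpha = config.draw_alpha(rng)
    bxse_v = np.broadcast_to(np.asarray(bxse, dtype=float), (j,)).copy()
    byse_v = np.broadcast_to(np.asarray(byse, dtype=float), (j,)).copy()
    bx = gamma + rng.normal(0.0, 1.0, j) * bxse_v
    by = config.theta * gamma + alpha + rng.normal(0.0, 1.0, j) * byse_v
    data = SummaryData(
        bx=bx,
        bxse=np.where(bxse_v > 0, bxse_v, 1e-12),
        by=by,
        byse=np.where(byse_v > 0, byse_v, 1e-12),
        variant_ids=tuple(f"snp_{k + 1}" for k in range(j)),
    )
    return SummaryTruth(data=data, theta=config.theta, gamma=gamma, alpha=alpha)
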