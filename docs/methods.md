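# Methods

This note records the statistical model behind each estimator, the
conventions and tunable constants the implementation commits to, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## Data model and harmonization

The universal input is per-variant summarized data: exposure-association
estimates bxⱼ with standard errors bxseⱼ, and outcome-association estimates
byⱼ with byseⱼ, for j = 1..J independent (or explicitly correlated)
variants. Standard errors must be strictly positive; estimators accept bare
betas, while the harmonization operations additionally require allele
labels.

**Allele alignment.** Two studies often report the same variant for
opposite alleles. `align_alleles` keeps the exposure side's effect allele as
the reference: an identical effect/other pair keeps the outcome beta, a
swapped pair negates it, and any other combination is irreconcilable —
dropped and reported rather than guessed. Reverse-complement ("strand")
matching is attempted only when `allow_strand_flip=True` and never for
palindromic (A/T, C/G) variants, whose allele pair maps onto itself under
complementation; resolving palindromes by allele frequency is deliberately
out of scope, so they are flagged (`flag_palindromic`) and left to the
analyst. Missing alleles yield an *indeterminate* flag (`None`), not
`False`, so absence of information is never mistaken for evidence of a
non-palindrome.

**Orientation.** MR-Egger's intercept is only meaningful if all variants
share an orientation, so `mr_egger` internally re-orients every variant to
its exposure-increasing allele (bx < 0 ⇒ negate bx and by, complement eaf,
swap allele labels, sign-adjust correlation rows/columns). A variant with
bx exactly 0 has no exposure-increasing allele; it is left unchanged (sign
convention +1). The per-variant ratio by/bx is invariant under orientation,
the operation is idempotent, and it is not exposed as a user switch on the
estimator: disabling it would silently change the meaning of the intercept.

**Correlation matrices** must be symmetric (tolerance 1e-10), unit-diagonal
and positive semi-definite down to eigenvalue −1e-8 — the slack admits
matrices estimated from finite reference panels, which are often very
slightly indefinite after rounding.

## Weights, heterogeneity and penalization

First-order weights wⱼ = 1/byseⱼ² ignore uncertainty in bx, as is standard
for IVW and MR-Egger; second-order or exact weights are intentionally not
offered. Cochran's Q = Σ wⱼ (byⱼ − a − θ bxⱼ)² with df = J − p (p = 1 for
IVW, 2 for Egger) tests whether the variant-specific estimates agree;
`residual_se = sqrt(Q/df)` is the residual standard error of the weighted
fit.

**Penalization** multiplies each weight by min(1, 20 pⱼ), where pⱼ is the
upper chi-square(1) tail at the variant's heterogeneity contribution
qⱼ = wⱼ(byⱼ − θ_ref bxⱼ)². With the multiplier 20 the factor is exactly 1
at the upper-5% quantile (3.8415) and decays smoothly beyond it, so
ordinary sampling variation is never penalized. The reference estimate
θ_ref is the unpenalized IVW estimate (for the penalized median: the
unpenalized weighted median), one pass, not iterated — deterministic and
sufficient for the penalty's purpose of bounding outlier influence. The
multiplier is exposed as `PENALTY_MULTIPLIER`.

**I²_GX** = max(0, (Q_GX − (J−1))/Q_GX), where Q_GX is the precision-
weighted dispersion of the oriented exposure associations, quantifies how
much of the spread in bx is signal rather than measurement error; values
well below 1 warn of regression-dilution (weak instrument) bias in the
MR-Egger slope. Negative raw values (under-dispersion) are truncated to 0
with a warning.

## Estimators

**IVW.** Weighted through-origin regression. J = 1 reduces to the Wald
ratio by/bx with SE byse/|bx|. Under the default multiplicative
random-effects model the raw SE (from the unscaled inverse normal matrix)
is inflated by max(1, residual_se); fixed effects report the raw SE. The
floor at 1 means under-dispersed data never *deflate* the SE, in either
mode, and the point estimate never differs between the two modes. t-based
inference uses J − 1 degrees of freedom.

**MR-Egger.** Weighted regression with intercept on oriented data, J ≥ 3
required; both parameters share the max(1, residual_se) inflation and J − 2
degrees of freedom.

**Correlated variants.** With an LD matrix ρ the residual covariance is
Σᵢⱼ = byseᵢ byseⱼ ρᵢⱼ and both IVW and Egger switch to generalized weighted
regression, β̂ = (XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹y, implemented by Cholesky whitening. Q
generalizes to the whitened residual sum of squares. Perfectly correlated
duplicates make Σ singular and raise an error suggesting pruning. Robust
and penalized options are rejected in combination with `correlated`: no
established construction exists for the former, and the latter's
per-variant chi-square contributions are undefined under a dense residual
covariance.

**Robust option.** The weighted problem (rows scaled by √w) is fitted by
iteratively reweighted least squares with a redescending Tukey biweight
psi-function (via statsmodels), giving every variant bounded influence; on
outlier-free data it agrees with weighted least squares. Its standard
errors come from the M-estimator's own scale, which already absorbs
overdispersion, so the fixed/random distinction does not further modify
them. Robust and penalized compose (weights are penalized first, then fed
to the robust fit).

**Median estimators.** Ratios θⱼ = byⱼ/bxⱼ; variants with bx = 0 are
dropped with a warning (never silently — their ratio is undefined). The
weighted percentile uses cumulative-midpoint positions
sₖ = (Σᵢ≤ₖ wᵢ − wₖ/2)/Σw with linear interpolation, chosen among the
textbook definitions because it makes the equal-weight case reduce exactly
to the ordinary sample median — the anchor every test can rely on. Weights:
equal (simple), bxⱼ²/byseⱼ² (weighted — the first-order inverse variance of
θⱼ), or penalized versions of the latter. The standard error is a
parametric bootstrap: bx*, by* drawn from normal distributions centred on
the observed values with the reported SEs, 1000 iterations by default,
fully determined by the seed; iterations in which the estimator fails are
dropped, and more than 10% failures abort. J ≥ 2 is required and a warning
is emitted below J = 10, where a median of ratios is hard to defend.

**Maximum likelihood.** (bxⱼ, byⱼ) ~ bivariate normal with mean
(ξⱼ, θξⱼ), SDs (bxseⱼ, byseⱼ) and correlation ψ between the two
measurement errors. ψ defaults to 0 — the two-sample, non-overlapping
setting — and is exposed for one-sample overlap. The J + 1 parameters are
maximized jointly by L-BFGS-B with the closed-form analytic gradient
(initialization ξⱼ = bxⱼ, θ = IVW), followed by Newton refinement using the
observed information until the Newton step is below 1e-10 relative — the
polish matters because with small SEs the likelihood is so sharply curved
that quasi-Newton methods stop with formally "abnormal" terminations at
already-converged points. SE(θ̂) is the square root of the θ-diagonal of
the inverse observed information (central-difference Hessian of the
analytic gradient, step 1e-5 relative). An overdispersed/random-effects
likelihood variant is intentionally not offered.

## Synthetic data

`simulate_individual_data` draws the canonical IV model: genotypes
gⱼ ~ Binomial(2, maf), a shared standard-normal confounder u, exposure
x = Σ γⱼ gⱼ + 0.5u + ε, outcome y = θx + Σ αⱼ gⱼ + 0.5u + ε. Defaults —
n = 10 000 individuals, J = 10 variants, maf 0.3, γ = 0.15 (per-variant
F ≈ 90), θ = 0.2, confounder loadings 0.5, unit noise — describe a
well-powered contemporary two-sample study with strong instruments.
Pleiotropy modes: `none`; `balanced` (αⱼ zero-mean normal); `directional`
(αⱼ positive-mean, drawn independently of γ so InSIDE holds; mean 0.05, sd
0.02 by default); `inside_violating` (αⱼ proportional to γⱼ plus noise).
`summarize_individual_data` reduces a cohort to marginal per-variant simple
regressions — exactly how GWAS summary statistics arise —
and `simulate_two_sample` uses two independent cohorts so the exposure and
outcome summaries are uncorrelated, as the estimators assume.
`simulate_summary_data` samples the summaries directly from their
asymptotic model (bxⱼ ~ N(γⱼ, bxse²), byⱼ ~ N(θγⱼ + αⱼ, byse²)), which is
what makes 1000-replicate coverage studies affordable.
`simulate_correlated_genotypes` induces LD through a Gaussian-copula
threshold on latent haplotypes; the realized genotype correlation is
attenuated relative to the latent target, which is adequate for exercising
the GLS code path but is not a model of human LD maps. Also not emulated:
case-control ascertainment (binary outcomes enter only as log odds ratios
via the direct summary generator), allele-frequency spectra, winner's-curse
selection of instruments, and sample overlap. Passing tests therefore
demonstrate correctness of the estimators under their own assumptions, not
robustness to these real-data complications.

`two_stage_least_squares` is the independent individual-level oracle
(stage 1: x on all genotypes jointly; stage 2: y on fitted x̂; conventional
2SLS variance using residuals at the observed exposure). The headline check
runs 50 seeded cohorts (n = 10 000, J = 10, no pleiotropy) and requires the
median relative IVW-vs-2SLS difference below 1%; measured values sit near
0.3%.

## Extraction workflow

`extract_pheno_csv` filters a long association table by (trait, PubMed ID,
ancestry) for each side, substitutes the best proxy (highest r², ties to
the lexicographically smallest rsid) for variants missing one side when
proxy r² ≥ the threshold (default 0.6), and hands the result to
`align_alleles`. The threshold comparison is inclusive (≥) so that a
threshold of 1.0 still admits perfect proxies. Proxy records carry the
proxy's own alleles and betas; no LD-sign adjustment is applied beyond
ordinary allele alignment. The association-table column schema is this
package's own documented dialect; exports from public databases need a
one-off column rename. Live database queries are out of scope.

## Study sizes used in the validation suite

The shipped checks use: 50 cohorts of n = 10 000 for the 2SLS equivalence;
1000 summary-level replicates (J = 20, strong instruments) for null
coverage, with the acceptance band [0.93, 0.97] around the nominal 0.95;
200 replicates each for the recovery scenarios (θ = 0.2; directional
pleiotropy mean 0.02; 40% one-sided pleiotropic weight for the median);
100 replicates for maximum-likelihood recovery, whose per-fit cost is the
highest; and 100–500 random instances for the algebraic oracle
comparisons at tolerance 1e-10. These sizes give Monte-Carlo standard
errors a few times smaller than the effects being verified while keeping
the whole suite runnable in seconds.

## Known limitations

Multivariable MR, mode-based estimators, Q-minimization weighting,
second-order weights, correlated-variant maximum likelihood and formal
outlier-removal procedures are not implemented. The weighted median's
bootstrap assumes normal sampling of the summary statistics; with very few
variants its SE is optimistic, hence the J < 10 warning. Palindromic
variants are flagged but never auto-resolved.
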