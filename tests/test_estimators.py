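"""IVW and MR-Egger estimators."""

import numpy as np
import pytest
from dataclasses import replace

from mrsummary import (
    CorrelationMatrix,
    EstimatorOptions,
    SummaryData,
    mr_egger,
    mr_ivw,
    orient_to_exposure_increasing,
    wls_with_intercept,
)
from mrsummary.exceptions import InsufficientVariantsError


def ivw_closed_form(data):
    """Hand-summation ratio-combination formula."""
    w = 1 / data.byse**2
    return float(np.sum(w * data.bx * data.by) / np.sum(w * data.bx**2))


class TestIvw:
    def test_single_variant_wald_ratio(self):
        d = SummaryData(bx=[-0.4], bxse=[0.05], by=[0.1], byse=[0.02])
        est = mr_ivw(d)
        assert est.estimate == pytest.approx(0.1 / -0.4)
        assert est.std_error == pytest.approx(0.02 / 0.4)
        assert est.heterogeneity is None

    def test_identical_instruments_give_mean(self):
        d = SummaryData(bx=[1, 1, 1], bxse=[0.1] * 3, by=[0.1, 0.2, 0.6],
                        byse=[0.5] * 3)
        assert mr_ivw(d).estimate == pytest.approx(np.mean([0.1, 0.2, 0.6]))

    def test_three_way_agreement_with_closed_form(self, small_data):
        est = mr_ivw(small_data)
        assert est.estimate == pytest.approx(ivw_closed_form(small_data), abs=1e-10)

    def test_random_se_geq_fixed_se(self, small_data):
        fixed = mr_ivw(small_data, EstimatorOptions(effects_model="fixed"))
        random = mr_ivw(small_data, EstimatorOptions(effects_model="random"))
        assert random.std_error >= fixed.std_error
        assert random.estimate == pytest.approx(fixed.estimate)

    def test_random_effects_inflation_floor(self):
        # heterogeneous data: residual SE > 1 inflates the random-effects SE
        d = SummaryData(bx=[0.2, 0.2, 0.2, 0.2], bxse=[0.01] * 4,
                        by=[0.01, 0.2, -0.15, 0.4], byse=[0.01] * 4)
        fixed = mr_ivw(d, EstimatorOptions(effects_model="fixed"))
        random = mr_ivw(d, EstimatorOptions(effects_model="random"))
        assert random.heterogeneity.residual_se > 1
        assert random.std_error == pytest.approx(
            fixed.std_error * random.heterogeneity.residual_se
        )

    def test_scale_equivariance(self, small_data):
        c = 3.5
        up = SummaryData(bx=small_data.bx, bxse=small_data.bxse,
                         by=c * small_data.by, byse=c * small_data.byse)
        est0, est1 = mr_ivw(small_data), mr_ivw(up)
        assert est1.estimate == pytest.approx(c * est0.estimate, rel=1e-12)
        assert est1.std_error == pytest.approx(c * est0.std_error, rel=1e-12)
        down = SummaryData(bx=c * small_data.bx, bxse=small_data.bxse,
                           by=small_data.by, byse=small_data.byse)
        assert mr_ivw(down).estimate == pytest.approx(est0.estimate / c, rel=1e-12)

    def test_identity_correlation_equals_plain(self, small_data):
        withcorr = replace(
            small_data, correlation=CorrelationMatrix(np.eye(len(small_data)))
        )
        a = mr_ivw(small_data)
        b = mr_ivw(withcorr, EstimatorOptions(correlated=True))
        assert b.estimate == pytest.approx(a.estimate, abs=1e-10)
        assert b.std_error == pytest.approx(a.std_error, abs=1e-10)

    def test_t_distribution_widens_ci(self, small_data):
        n = mr_ivw(small_data, EstimatorOptions(distribution="normal"))
        t = mr_ivw(small_data, EstimatorOptions(distribution="t"))
        assert t.ci_lower < n.ci_lower and t.ci_upper > n.ci_upper

    def test_penalization_downweights_outlier(self):
        bx = np.full(10, 0.2)
        by = 0.3 * bx
        by[0] = 1.0  # grossly heterogeneous variant
        d = SummaryData(bx=bx, bxse=np.full(10, 0.01), by=by,
                        byse=np.full(10, 0.1))
        pen = mr_ivw(d, EstimatorOptions(penalized=True))
        plain = mr_ivw(d)
        assert abs(pen.estimate - 0.3) < abs(plain.estimate - 0.3)
        assert pen.estimate == pytest.approx(0.3, abs=1e-6)

    def test_robust_correlated_rejected(self):
        with pytest.raises(ValueError, match="robust"):
            EstimatorOptions(robust=True, correlated=True)


class TestEgger:
    def test_noiseless_linear_data(self):
        rng = np.random.default_rng(31)
        bx = rng.uniform(0.1, 0.5, 6)
        d = SummaryData(bx=bx, bxse=[0.01] * 6, by=0.1 + 0.3 * bx,
                        byse=[0.02] * 6)
        est = mr_egger(d)
        assert est.estimate == pytest.approx(0.3, abs=1e-10)
        assert est.intercept.estimate == pytest.approx(0.1, abs=1e-10)
        assert est.heterogeneity.Q == pytest.approx(0.0, abs=1e-16)

    def test_orientation_invariance(self, small_data):
        mirrored = SummaryData(bx=-small_data.bx, bxse=small_data.bxse,
                               by=-small_data.by, byse=small_data.byse)
        a, b = mr_egger(small_data), mr_egger(mirrored)
        assert b.estimate == pytest.approx(a.estimate, rel=1e-12)
        assert b.intercept.estimate == pytest.approx(a.intercept.estimate, rel=1e-12)

    def test_mixed_sign_bx_matches_oracle_on_oriented_data(self):
        rng = np.random.default_rng(37)
        bx = rng.normal(0, 0.3, 20)
        by = rng.normal(0, 0.1, 20)
        d = SummaryData(bx=bx, bxse=np.full(20, 0.01), by=by,
                        byse=rng.uniform(0.01, 0.05, 20))
        est = mr_egger(d)
        o = orient_to_exposure_increasing(d)
        oracle = wls_with_intercept(o.bx, o.by, 1 / o.byse**2)
        assert est.estimate == pytest.approx(oracle.slope, abs=1e-12)
        assert est.intercept.estimate == pytest.approx(oracle.intercept, abs=1e-12)

    def test_directional_pleiotropy_recovered(self):
        """Constant pleiotropy 0.05 with InSIDE: intercept -> 0.05, slope ->
        theta, checked against the closed-form WLS oracle on oriented data."""
        rng = np.random.default_rng(41)
        j = 100
        gamma = rng.uniform(0.05, 0.5, j)
        bxse = np.full(j, 1e-4)
        byse = np.full(j, 1e-3)
        bx = gamma + rng.normal(0, 1, j) * bxse
        by = 0.2 * gamma + 0.05 + rng.normal(0, 1, j) * byse
        d = SummaryData(bx=bx, bxse=bxse, by=by, byse=byse)
        est = mr_egger(d)
        assert est.estimate == pytest.approx(0.2, abs=5e-3)
        assert est.intercept.estimate == pytest.approx(0.05, abs=2e-3)

    def test_too_few_variants(self):
        d = SummaryData(bx=[0.1, 0.2], bxse=[0.01] * 2, by=[0.0, 0.1],
                        byse=[0.01] * 2)
        with pytest.raises(InsufficientVariantsError):
            mr_egger(d)

    def test_i_squared_attached(self, small_data):
        est = mr_egger(small_data)
        assert 0.0 <= est.i_squared_gx <= 1.0

    def test_heterogeneity_df(self, small_data):
        est = mr_egger(small_data)
        assert est.heterogeneity.df == len(small_data) - 2

    def test_balanced_pleiotropy_intercept_shrinks(self):
        """Symmetric pleiotropy about the causal line: intercept near 0 at
        large J with precise associations."""
        rng = np.random.default_rng(43)
        j = 500
        gamma = rng.uniform(0.1, 0.5, j)
        alpha = rng.normal(0.0, 0.01, j)
        bx = gamma
        by = 0.2 * gamma + alpha
        d = SummaryData(bx=bx, bxse=np.full(j, 1e-5), by=by,
                        byse=np.full(j, 1e-2))
        est = mr_egger(d)
        assert est.intercept.estimate == pytest.approx(0.0, abs=3e-3)
        assert est.estimate == pytest.approx(0.2, abs=2e-2)

    def test_correlated_identity_matches_plain(self, small_data):
        withcorr = replace(
            small_data, correlation=CorrelationMatrix(np.eye(len(small_data)))
        )
        a = mr_egger(small_data)
        b = mr_egger(withcorr, EstimatorOptions(correlated=True))
        assert b.estimate == pytest.approx(a.estimate, abs=1e-10)
        assert b.intercept.estimate == pytest.approx(a.intercept.estimate, abs=1e-10)
        assert b.std_error == pytest.approx(a.std_error, abs=1e-10)
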