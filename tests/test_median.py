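"""Median-based estimators and the parametric bootstrap."""

import numpy as np
import pytest

from mrsummary import (
    BootstrapConfig,
    SummaryData,
    bootstrap_se,
    mr_median,
    weighted_percentile,
)
from mrsummary.exceptions import DegenerateDesignError


def cdf_oracle(values, weights, p):
    """Brute-force scan of the piecewise-linear weighted CDF.

    Builds the (position, value) knots exactly as defined — positions are
    cumulative weight midpoints — and evaluates the inverse CDF at p by
    explicit segment search rather than vectorized interpolation.
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    total = w.sum()
    s = []
    run = 0.0
    for wi in w:
        s.append((run + wi / 2.0) / total)
        run += wi
    if p <= s[0]:
        return v[0]
    if p >= s[-1]:
        return v[-1]
    for k in range(len(s) - 1):
        if s[k] <= p <= s[k + 1]:
            if s[k + 1] == s[k]:
                return v[k]
            frac = (p - s[k]) / (s[k + 1] - s[k])
            return v[k] + frac * (v[k + 1] - v[k])
    raise AssertionError("unreachable")


class TestWeightedPercentile:
    def test_odd_count_median(self):
        assert weighted_percentile([1, 2, 3], [1, 1, 1], 0.5) == 2.0

    def test_two_values_interpolate(self):
        # midpoints 0.25 and 0.75 -> p = 0.5 interpolates to 1.5
        assert weighted_percentile([1, 2], [1, 1], 0.5) == pytest.approx(1.5)

    def test_dominant_weight(self):
        assert weighted_percentile([1, 2, 9], [1, 50, 1], 0.5) == pytest.approx(2.0)

    def test_all_zero_weights_error(self):
        with pytest.raises(DegenerateDesignError):
            weighted_percentile([1, 2], [0, 0], 0.5)

    def test_matches_cdf_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(500):
            n = int(rng.integers(2, 12))
            v = rng.normal(size=n)
            w = rng.uniform(0.01, 3, n)
            p = float(rng.uniform())
            assert weighted_percentile(v, w, p) == pytest.approx(
                cdf_oracle(v, w, p), abs=1e-12
            )

    def test_equal_weights_match_sample_median(self):
        rng = np.random.default_rng(53)
        for _ in range(100):
            n = int(rng.integers(2, 15))
            v = rng.normal(size=n)
            got = weighted_percentile(v, np.ones(n), 0.5)
            assert got == pytest.approx(np.median(v), abs=1e-12)


def _strong_data(rng, j=12, theta=0.25):
    gamma = rng.uniform(0.1, 0.4, j)
    bxse = np.full(j, 0.005)
    byse = rng.uniform(0.005, 0.01, j)
    bx = gamma + rng.normal(0, 1, j) * bxse
    by = theta * gamma + rng.normal(0, 1, j) * byse
    return SummaryData(bx=bx, bxse=bxse, by=by, byse=byse)


class TestMrMedian:
    def test_simple_median_middle_ratio(self):
        d = SummaryData(bx=[1, 1, 1], bxse=[0.01] * 3, by=[0.1, 0.2, 0.9],
                        byse=[0.1] * 3)
        with pytest.warns(UserWarning, match="only 3 variants"):
            est = mr_median(d, "simple", bootstrap=BootstrapConfig(50, 0))
        assert est.estimate == pytest.approx(0.2)

    def test_weighted_collapses_to_dominant_variant(self):
        # one variant carries nearly all weight -> its ratio
        d = SummaryData(bx=[1, 1, 1], bxse=[0.01] * 3, by=[0.1, 0.5, 0.9],
                        byse=[1e-4, 10.0, 10.0])
        with pytest.warns(UserWarning):
            est = mr_median(d, "weighted", bootstrap=BootstrapConfig(50, 0))
        assert est.estimate == pytest.approx(0.1, abs=1e-6)

    def test_equal_weight_case_equals_simple(self):
        rng = np.random.default_rng(59)
        j = 11
        bx = rng.uniform(0.2, 0.4, j)
        byse = 0.05 * bx  # bx^2/byse^2 constant -> weighted == simple
        d = SummaryData(bx=bx, bxse=np.full(j, 0.01),
                        by=rng.normal(0.1, 0.05, j), byse=byse)
        boot = BootstrapConfig(10, 0)
        simple = mr_median(d, "simple", bootstrap=boot).estimate
        weighted = mr_median(d, "weighted", bootstrap=boot).estimate
        assert weighted == pytest.approx(simple, abs=1e-12)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(61)
        d = _strong_data(rng)
        flip = rng.random(len(d)) < 0.5
        s = np.where(flip, -1.0, 1.0)
        d2 = SummaryData(bx=d.bx * s, bxse=d.bxse, by=d.by * s, byse=d.byse)
        boot = BootstrapConfig(10, 3)
        for variant in ("simple", "weighted", "penalized"):
            a = mr_median(d, variant, bootstrap=boot).estimate
            b = mr_median(d2, variant, bootstrap=boot).estimate
            assert b == pytest.approx(a, abs=1e-12)

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(67)
        for _ in range(25):
            d = _strong_data(rng, j=int(rng.integers(3, 15)))
            theta = d.by / d.bx
            est = mr_median(d, "weighted", bootstrap=BootstrapConfig(5, 0))
            assert theta.min() - 1e-12 <= est.estimate <= theta.max() + 1e-12

    def test_breakdown_under_minority_corruption(self):
        """Corrupting variants carrying <50% of weight by +1e6 leaves the
        weighted median inside the original ratio range."""
        rng = np.random.default_rng(71)
        d = _strong_data(rng, j=15)
        w = d.bx**2 / d.byse**2
        order = np.argsort(w)
        corrupt = []
        acc = 0.0
        for idx in order:  # take lightest variants until just under 45%
            if acc + w[idx] < 0.45 * w.sum():
                corrupt.append(idx)
                acc += w[idx]
        by = d.by.copy()
        by[corrupt] += 1e6
        theta_clean = d.by / d.bx
        d2 = SummaryData(bx=d.bx, bxse=d.bxse, by=by, byse=d.byse)
        est = mr_median(d2, "weighted", bootstrap=BootstrapConfig(5, 0))
        assert theta_clean.min() <= est.estimate <= theta_clean.max()

    def test_bx_zero_dropped_with_warning(self):
        d = SummaryData(bx=[0.0, 0.3, 0.2, 0.25], bxse=[0.01] * 4,
                        by=[9.9, 0.06, 0.05, 0.06], byse=[0.01] * 4)
        with pytest.warns(UserWarning, match="bx = 0"):
            est = mr_median(d, "simple", bootstrap=BootstrapConfig(20, 0))
        assert est.n_variants == 3
        assert est.estimate < 1  # the undefined-ratio variant did not leak in

    def test_all_bx_zero_errors(self):
        d = SummaryData(bx=[0.0, 0.0], bxse=[0.01] * 2, by=[1, 2],
                        byse=[0.01] * 2)
        with pytest.raises(Exception):
            mr_median(d, "simple", bootstrap=BootstrapConfig(5, 0))

    def test_penalized_ignores_outlying_ratio(self):
        rng = np.random.default_rng(73)
        d = _strong_data(rng, j=20, theta=0.25)
        by = d.by.copy()
        by[0] = d.bx[0] * 5.0  # ratio 5 vs 0.25 elsewhere
        d2 = SummaryData(bx=d.bx, bxse=d.bxse, by=by, byse=d.byse)
        boot = BootstrapConfig(50, 0)
        with np.errstate(all="ignore"):
            pen = mr_median(d2, "penalized", bootstrap=boot)
        assert pen.estimate == pytest.approx(0.25, abs=0.02)


class TestBootstrap:
    def test_deterministic_given_seed(self, small_data):
        boot = BootstrapConfig(200, 42)
        a = mr_median(small_data, "weighted", bootstrap=boot)
        b = mr_median(small_data, "weighted", bootstrap=boot)
        assert a.std_error == b.std_error

    def test_degenerate_no_noise_gives_zero_se(self):
        d = SummaryData(bx=[0.2, 0.3, 0.4], bxse=[1e-300] * 3,
                        by=[0.05, 0.075, 0.1], byse=[1e-300] * 3)
        se = bootstrap_se(
            d, lambda s: float(np.median(s.by / s.bx)), BootstrapConfig(50, 0)
        )
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_against_monte_carlo(self):
        """Bootstrap SE within 30% of the empirical SD of the weighted
        median across fresh datasets from the same generating model."""
        rng = np.random.default_rng(79)
        j = 50
        gamma = rng.uniform(0.1, 0.4, j)
        bxse = np.full(j, 0.01)
        byse = np.full(j, 0.02)

        def draw(r):
            bx = gamma + r.normal(0, 1, j) * bxse
            by = 0.2 * gamma + r.normal(0, 1, j) * byse
            return SummaryData(bx=bx, bxse=bxse, by=by, byse=byse)

        def est(d):
            theta = d.by / d.bx
            w = d.bx**2 / d.byse**2
            return weighted_percentile(theta, w, 0.5)

        empirical = np.std([est(draw(rng)) for _ in range(500)], ddof=1)
        boot = bootstrap_se(draw(rng), est, BootstrapConfig(1000, 5))
        assert boot == pytest.approx(empirical, rel=0.3)
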