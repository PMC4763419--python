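"""Discrimination and calibration metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_auroc
from traumarisk.performance import (
    auroc,
    calibration_plot_data,
    calibration_slope,
    compare_auroc,
    compare_calibration_slope,
    pool_metric,
    sens_spec,
)


class TestAuroc:
    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 200))
    def test_matches_all_pairs_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        p = rng.choice([0.1, 0.25, 0.5, 0.9], size=n)  # force ties
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auroc(p, y) == pytest.approx(brute_force_auroc(p, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        p = rng.random(300)
        y = rng.integers(0, 2, 300)
        assert auroc(p, y) == pytest.approx(auroc(np.exp(3 * p), y), abs=1e-12)


class TestCompareAuroc:
    def test_identical_predictions_return_one(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        y = rng.integers(0, 2, 100)
        assert compare_auroc(p, p, y) == 1.0

    def test_informative_vs_noise_is_significant(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 2000
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(2 * x - 1)))).astype(int)
            noise = rng.random(n)
            p_info = 1 / (1 + np.exp(-x))
            if compare_auroc(p_info, noise, y) < 0.001:
                hits += 1
        assert hits >= 4

    def test_type_one_error_near_alpha(self):
        """Two equally informative correlated predictors: rejection at 5%
        should be near 5% (binomial 3 SE band around 0.05, 200 repeats)."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            n = 400
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
            if y.min() == y.max():
                continue
            p_a = 1 / (1 + np.exp(-(x + rng.standard_normal(n))))
            p_b = 1 / (1 + np.exp(-(x + rng.standard_normal(n))))
            if compare_auroc(p_a, p_b, y) < 0.05:
                rejections += 1
        rate = rejections / reps
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / reps))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_auroc([0.1, 0.2], [0.1], [0, 1])


class TestCalibrationSlope:
    def test_linear_reparameterisation_identity(self):
        rng = np.random.default_rng(3)
        lp = rng.standard_normal(2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-lp))).astype(float)
        s1 = calibration_slope(lp, y)
        s2 = calibration_slope(2 * lp, y)
        assert s2 == pytest.approx(s1 / 2, abs=1e-8)

    def test_overfit_model_slope_below_one(self):
        """A model overfit on a small sample has slope < 1 on fresh data."""
        import statsmodels.api as sm

        below = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_fit, n_val, p = 120, 4000, 8
            X = rng.standard_normal((n_fit, p))
            beta = np.array([0.5, -0.4, 0.3, 0, 0, 0, 0, 0])
            y = (rng.random(n_fit) < 1 / (1 + np.exp(-(X @ beta - 1)))).astype(float)
            try:
                fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
            except Exception:
                continue
            Xv = rng.standard_normal((n_val, p))
            yv = (rng.random(n_val) < 1 / (1 + np.exp(-(Xv @ beta - 1)))).astype(float)
            lp_v = sm.add_constant(Xv) @ fit.params
            if calibration_slope(lp_v, yv) < 1:
                below += 1
        assert below >= 9


class TestCompareCalibrationSlope:
    def test_identical_lp_returns_one(self):
        rng = np.random.default_rng(4)
        lp = rng.standard_normal(500)
        y = (rng.random(500) < 0.3).astype(float)
        assert compare_calibration_slope(lp, lp, y) == 1.0

    def test_badly_scaled_lp_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 5000
            lp = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
            if compare_calibration_slope(lp, 2 * lp, y, n_boot=400, seed=seed) < 0.01:
                hits += 1
        assert hits >= 4

    def test_null_retains_nominal_level(self):
        """Equal-slope null: rejection rate at 5% within 3 binomial SE."""
        reps, rejections = 100, 0
        for seed in range(reps):
            rng = np.random.default_rng(20_000 + seed)
            n = 600
            x = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
            lp_a = x + 0.5 * rng.standard_normal(n)
            lp_b = x + 0.5 * rng.standard_normal(n)
            if compare_calibration_slope(lp_a, lp_b, y, n_boot=199, seed=seed) < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(
            0.05, abs=3 * np.sqrt(0.05 * 0.95 / reps)
        )


class TestSensSpec:
    def test_threshold_zero_everyone_positive(self):
        sens, spec = sens_spec([0.1, 0.9], [1, 0], threshold=0.0)
        assert sens == 1.0 and spec == 0.0

    def test_threshold_above_one_everyone_negative(self):
        sens, spec = sens_spec([0.1, 0.9], [1, 0], threshold=1.0001)
        assert sens == 0.0 and spec == 1.0

    def test_worked_confusion_table(self):
        # p >= 0.05: patients 2 and 4 positive; both are the true cases
        sens, spec = sens_spec([0.01, 0.2, 0.04, 0.9], [0, 1, 0, 1], threshold=0.05)
        assert (sens, spec) == (1.0, 1.0)

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 100)
        p = rng.random(n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        t = float(rng.random())
        sens, spec = sens_spec(p, y, t)
        tp = sum(1 for pi, yi in zip(p, y) if pi >= t and yi == 1)
        fn = sum(1 for pi, yi in zip(p, y) if pi < t and yi == 1)
        tn = sum(1 for pi, yi in zip(p, y) if pi < t and yi == 0)
        fp = sum(1 for pi, yi in zip(p, y) if pi >= t and yi == 0)
        assert sens == tp / (tp + fn) and spec == tn / (tn + fp)


class TestCalibrationPlotData:
    def test_perfectly_calibrated_large_sample(self):
        rng = np.random.default_rng(5)
        n = 50_000
        p = rng.beta(2, 20, n)
        y = (rng.random(n) < p).astype(float)
        data = calibration_plot_data(p, y)
        dev = np.abs(
            np.asarray(data.mean_predicted) - np.asarray(data.observed_fraction)
        )
        assert dev.max() < 0.02

    def test_groups_partition_with_near_equal_sizes(self):
        rng = np.random.default_rng(6)
        p = rng.random(105)
        y = rng.integers(0, 2, 105)
        data = calibration_plot_data(p, y)
        assert sum(data.group_sizes) == 105
        assert max(data.group_sizes) - min(data.group_sizes) <= 1

    def test_degenerate_one_patient_groups(self):
        p = np.linspace(0.1, 0.9, 10)
        y = np.array([0, 1] * 5)
        data = calibration_plot_data(p, y, n_groups=10)
        assert set(data.observed_fraction) <= {0.0, 1.0}

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            calibration_plot_data([0.5, 0.2], [0, 1], n_groups=10)


def test_pool_metric_median_within_iqr():
    med, (q1, q3) = pool_metric([0.84, 0.85, 0.83, 0.86])
    assert q1 <= med <= q3
    with pytest.raises(ValueError):
        pool_metric([])
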