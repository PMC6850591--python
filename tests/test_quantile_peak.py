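"""Quantile-spline ceilings, bootstrap T_opt, shape classes, chi-square."""

import numpy as np
import pytest

from thermoniche import quantile_peak as qp
from conftest import make_frame


class TestFitQuantileSpline:
    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            qp.fit_quantile_spline(np.linspace(0, 1, 7), np.zeros(7))

    def test_zero_temperature_range_rejected(self):
        with pytest.raises(ValueError):
            qp.fit_quantile_spline(np.full(50, 20.0), np.random.default_rng(0).normal(size=50))

    def test_constant_quantile_truth_flat_curve(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(10, 30, 1000)
        y = rng.normal(0, 1, 1000)
        curve = qp.fit_quantile_spline(x, y, seed=0)
        q80 = np.quantile(y, 0.8)
        iqr = np.subtract(*np.percentile(y, [75, 25]))
        assert np.max(np.abs(curve.fitted - q80)) <= 0.1 * iqr

    def test_pinball_coverage_near_tau(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(5, 25, 1000)
        y = 5 * np.exp(-(((x - 15) / 4) ** 2)) + rng.normal(0, 1, 1000)
        curve = qp.fit_quantile_spline(x, y, seed=1)
        frac_below = (y < curve.predict(x)).mean()
        assert 0.75 <= frac_below <= 0.85

    def test_duplicating_observations_leaves_curve_unchanged(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 120)
        y = x * 0.3 + rng.normal(0, 0.5, 120)
        a = qp.fit_quantile_spline(x, y, smoothing_parameter=0.01)
        b = qp.fit_quantile_spline(np.r_[x, x], np.r_[y, y], smoothing_parameter=0.01)
        assert np.allclose(a.fitted, b.fitted, atol=1e-5)

    def test_cv_tie_prefers_smallest_lambda(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 100)
        y = rng.normal(size=100)
        curve = qp.fit_quantile_spline(x, y, lambda_grid=np.array([0.5]))
        assert curve.smoothing_parameter == 0.5


class TestBootstrapTopt:
    def _frame(self, n_sites=600, topt=18.0, sigma=2.5, pi=0.15, peak=12.0,
               halfspan=8.0, seed=0):
        # zero-inflated split-Gaussian counts over a buffered thermal span,
        # the same process the generator uses
        rng = np.random.default_rng(seed)
        sst = rng.uniform(topt - halfspan, topt + halfspan, n_sites)
        counts = rng.poisson(peak * np.exp(-(((sst - topt) / sigma) ** 2))).astype(float)
        counts[rng.random(n_sites) < pi] = 0
        return make_frame(
            sst, counts,
            depth=rng.normal(10, 2, n_sites),
            protection=rng.integers(0, 3, n_sites),
            cov_1=rng.normal(size=n_sites),
            cov_2=rng.normal(size=n_sites),
        )

    def test_no_subsampling_when_absences_scarce(self):
        frame = self._frame(n_sites=400, sigma=6.0, pi=0.05)  # wide niche, few zeros
        assert frame.is_absence.sum() <= (~frame.is_absence).sum()
        est = qp.bootstrap_topt(frame, ["cov_1", "cov_2"], n_boot=25, seed=0)
        assert est.n_boot == 1
        assert len(est.per_boot_topt) == 1

    def test_recovers_symmetric_peak(self):
        frame = self._frame(n_sites=1200, topt=20.0, sigma=2.0, seed=1)
        assert (~frame.is_absence).sum() >= 350
        est = qp.bootstrap_topt(frame, ["cov_1", "cov_2"], n_boot=10, seed=1)
        assert abs(est.topt - 20.0) <= 1.0

    def test_deterministic_under_seed(self):
        frame = self._frame()
        a = qp.bootstrap_topt(frame, ["cov_1", "cov_2"], n_boot=5, seed=3)
        b = qp.bootstrap_topt(frame, ["cov_1", "cov_2"], n_boot=5, seed=3)
        assert a.per_boot_topt == b.per_boot_topt
        assert np.array_equal(a.curve.fitted, b.curve.fitted)

    def test_topt_within_grid(self):
        frame = self._frame(seed=4)
        est = qp.bootstrap_topt(frame, ["cov_1", "cov_2"], n_boot=3, seed=4)
        assert est.curve.grid[0] <= est.topt <= est.curve.grid[-1]


class TestTemperatureEffectTest:
    def test_identical_residuals_give_p_one(self):
        x = np.linspace(0, 10, 60)
        p = qp.temperature_effect_test(x, np.full(60, 2.0), n_perm=19, seed=0)
        assert p == 1.0

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(5, 25, 500)
        y = 20 * np.exp(-(((x - 15) / 3) ** 2)) + rng.normal(0, 1, 500)
        p = qp.temperature_effect_test(x, y, n_perm=199, seed=1)
        assert p <= 0.01

    def test_null_calibration_roughly_uniform(self):
        # independent residuals: p should not pile up near 0
        rng = np.random.default_rng(2)
        ps = []
        for k in range(40):
            x = rng.uniform(0, 20, 120)
            y = rng.normal(size=120)
            ps.append(qp.temperature_effect_test(x, y, n_perm=49, seed=k))
        assert (np.array(ps) <= 0.05).mean() <= 0.2
        assert np.median(ps) > 0.2


def _curve(grid, values):
    return qp.QuantileCurve(
        grid=np.asarray(grid, float), fitted=np.asarray(values, float),
        basis_dim=4, smoothing_parameter=0.0, tau=0.8,
    )


class TestClassifyShape:
    def test_constant_curve_no_trend(self):
        g = np.linspace(10, 30, 100)
        got = qp.classify_shape(_curve(g, np.full(100, 3.0)), 12, 28)
        assert got.label == "no_trend"
        assert got.rel_abund_cool_edge == pytest.approx(1.0)

    def test_symmetric_gaussian_two_sigma_edges_abundant_centre(self):
        g = np.linspace(10, 30, 401)
        vals = np.exp(-(((g - 20) / 2.5) ** 2) / 2)
        got = qp.classify_shape(_curve(g, vals), 15.0, 25.0)  # +-2 sigma
        assert got.label == "abundant_centre"
        assert got.rel_abund_cool_edge == pytest.approx(np.exp(-2.0), abs=0.01)
        assert got.rel_abund_warm_edge == pytest.approx(np.exp(-2.0), abs=0.01)

    def test_monotone_rising_is_warm_skewed(self):
        g = np.linspace(10, 30, 100)
        got = qp.classify_shape(_curve(g, g.copy()), 12, 28)
        assert got.label == "warm_skewed"
        assert got.rel_abund_warm_edge >= 0.75
        assert got.rel_abund_cool_edge < 0.75

    def test_monotone_falling_is_cool_skewed(self):
        g = np.linspace(10, 30, 100)
        got = qp.classify_shape(_curve(g, -g), 12, 28)
        assert got.label == "cool_skewed"

    def test_flat_zero_curve_no_trend(self):
        g = np.linspace(0, 1, 50)
        assert qp.classify_shape(_curve(g, np.zeros(50)), 0.2, 0.8).label == "no_trend"

    def test_negative_residual_curves_shifted_before_scaling(self):
        g = np.linspace(0, 10, 100)
        vals = -5 + 4 * np.exp(-(((g - 5) / 1.5) ** 2))
        got = qp.classify_shape(_curve(g, vals), 1.0, 9.0)
        assert got.label == "abundant_centre"

    def test_edges_outside_grid_are_clamped(self):
        g = np.linspace(10, 30, 100)
        got = qp.classify_shape(_curve(g, g.copy()), 5.0, 35.0)
        assert got.label == "warm_skewed"

    def test_invalid_edges_rejected(self):
        g = np.linspace(0, 1, 50)
        with pytest.raises(ValueError):
            qp.classify_shape(_curve(g, np.ones(50)), 0.8, 0.2)


class TestShapeProportions:
    def test_equal_counts_chi2_zero(self):
        labels = ["no_trend", "abundant_centre", "warm_skewed", "cool_skewed"] * 100
        chi2, df, p = qp.shape_proportions_test(labels)
        assert chi2 == pytest.approx(0.0)
        assert df == 3
        assert p == pytest.approx(1.0)

    def test_matches_hand_arithmetic(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 100, size=4)
        labels = [l for l, c in zip(qp.SHAPE_LABELS, counts) for _ in range(c)]
        chi2, df, _ = qp.shape_proportions_test(labels)
        e = counts.sum() / 4
        assert chi2 == pytest.approx(((counts - e) ** 2 / e).sum())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qp.shape_proportions_test([])

    def test_accepts_shape_class_objects(self):
        labels = [qp.ShapeClass("warm_skewed", 0.2, 0.9, 0.75)] * 8
        chi2, df, p = qp.shape_proportions_test(labels)
        assert chi2 == pytest.approx(24.0)  # all mass in one of four cells
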