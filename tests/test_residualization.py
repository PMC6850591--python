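"""First-stage models: PCA retention, ZIP likelihood, residuals, Mantel."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from thermoniche import residualization as rz


class TestSpeciesPca:
    def test_perfectly_correlated_covariates_single_axis(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        res = rz.species_pca(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert list(res.retained_axes) == [0]

    def test_independent_covariates_share_variance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(10_000, 5)), columns=list("abcde"))
        res = rz.species_pca(X)
        assert np.all((res.variance_fraction > 0.15) & (res.variance_fraction < 0.25))
        assert len(res.retained_axes) == 5

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = rz.species_pca(pd.DataFrame(rng.normal(size=(100, 6))))
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_retention_is_strict_inequality(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(500, 4)))
        res = rz.species_pca(X, retention=0.10)
        for ax in res.retained_axes:
            assert res.variance_fraction[ax] > 0.10
        excluded = set(range(len(res.variance_fraction))) - set(res.retained_axes)
        for ax in excluded:
            assert res.variance_fraction[ax] <= 0.10

    def test_constant_covariate_dropped(self, caplog):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50), "c": 1.0})
        res = rz.species_pca(X)
        assert res.columns == ["a", "b"]
        with pytest.raises(ValueError):
            rz.species_pca(pd.DataFrame({"a": np.ones(50), "b": np.ones(50)}))

    def test_reconstruction_of_standardized_matrix(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5)) * [1, 3, 0.5, 2, 1] + [0, 5, -2, 1, 0]
        res = rz.species_pca(pd.DataFrame(X))
        Xs = (X - X.mean(0)) / X.std(0)
        assert np.allclose(res.scores @ res.loadings.T, Xs, atol=1e-8)


def _zip_sample(n, pi, b0, b1, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(b0 + b1 * x)).astype(float)
    y[rng.random(n) < pi] = 0
    return x, y


class TestFitZip:
    def test_simulation_recovery_within_3se(self):
        x, y = _zip_sample(5000, pi=0.3, b0=1.0, b1=0.5, seed=0)
        fit = rz.fit_zip(y, x[:, None], ["x"])
        assert not fit.fallback
        for est, se, truth in zip(fit.count_params, fit.count_params_se, [1.0, 0.5]):
            assert abs(est - truth) <= 3 * se
        assert abs(fit.pi - 0.3) <= 3 * fit.infl_logit_se * 0.3 * 0.7 + 0.02

    def test_zero_inflation_truth_reduces_to_poisson(self):
        import statsmodels.api as sm

        x, y = _zip_sample(3000, pi=0.0, b0=0.3, b1=0.4, seed=1)
        fit = rz.fit_zip(y, x[:, None], ["x"])
        pois = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
        assert fit.pi < 0.03
        assert np.allclose(fit.count_params, pois.params, atol=0.05)

    def test_loglik_dominates_intercept_only(self):
        import statsmodels.api as sm

        x, y = _zip_sample(2000, pi=0.25, b0=0.8, b1=0.6, seed=2)
        fit = rz.fit_zip(y, x[:, None], ["x"])
        null = sm.ZeroInflatedPoisson(
            y, np.ones((len(y), 1)), exog_infl=np.ones((len(y), 1))
        ).fit(disp=0)
        assert fit.loglik >= null.llf

    def test_all_positive_or_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rz.fit_zip(np.ones(50), np.random.default_rng(0).normal(size=(50, 1)))


class TestExtractResiduals:
    def test_hand_computed_means(self):
        fit = rz.ZipFit(
            count_params=np.array([0.5, 0.2]), infl_logit=-1.0,
            loglik=0.0, converged=True, fallback=False, design_columns=["x"],
        )
        design = np.array([[0.0], [1.0], [2.0]])
        y = np.array([2.0, 0.0, 5.0])
        pi = expit(-1.0)
        mu = (1 - pi) * np.exp(0.5 + 0.2 * design[:, 0])
        assert np.allclose(rz.extract_residuals(fit, y, design), y - mu)

    def test_residuals_sum_near_zero_with_intercept(self):
        x, y = _zip_sample(4000, pi=0.2, b0=1.2, b1=0.3, seed=3)
        fit = rz.fit_zip(y, x[:, None], ["x"])
        resid = rz.extract_residuals(fit, y, x[:, None])
        assert abs(resid.sum()) <= 1e-3 * len(y) * y.mean()

    def test_no_covariate_effect_leaves_no_temperature_signal(self):
        # abundance independent of everything: residualization must not
        # manufacture a correlation with temperature
        rng = np.random.default_rng(6)
        n = 2000
        frame = pd.DataFrame(
            {
                "abundance": rng.poisson(4.0, n).astype(float),
                "is_absence": False,
                "sst": rng.uniform(5, 30, n),
                "depth": rng.normal(10, 2, n),
                "protection": rng.integers(0, 3, n),
                "cov_1": rng.normal(size=n),
                "cov_2": rng.normal(size=n),
                "cov_3": rng.normal(size=n),
            }
        )
        frame.loc[:49, "abundance"] = 0.0  # ZIP needs some zeros
        resid, fit, _ = rz.residualize_frame(frame, ["cov_1", "cov_2", "cov_3"])
        corr = np.corrcoef(resid, frame["sst"])[0, 1]
        assert abs(corr) < 0.05


class TestMantel:
    def test_identical_matrices_max_r_min_p(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 2))
        D = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        r, p = rz.mantel_test(D, D.copy(), n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_small_matrix_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        def dist(n):
            pts = rng.normal(size=(n, 2))
            return np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))

        D1, D2 = dist(4), dist(4)
        il = np.tril_indices(4, k=-1)
        v1 = D1[il]
        r_obs = np.corrcoef(v1, D2[il])[0, 1]
        count = sum(
            np.corrcoef(v1, D2[np.ix_(p, p)][il])[0, 1] >= r_obs
            for p in map(list, itertools.permutations(range(4)))
        )
        exact_p = count / 24
        # estimate with many permutations; random perms of S4 hit each of
        # the 24 elements uniformly, so p-hat converges to (1+k*24)/(n+1)
        r, p = rz.mantel_test(D1, D2, n_perm=9999, seed=2)
        assert r == pytest.approx(r_obs)
        assert abs(p - exact_p) < 0.03

    def test_agrees_with_skbio_statistic(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(3)
        def dist(n):
            pts = rng.normal(size=(n, 3))
            return np.hypot(
                *(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1)[:2]
            ) + np.abs(pts[:, None, 2] - pts[None, :, 2])

        D1, D2 = dist(20), dist(20)
        r, _ = rz.mantel_test(D1, D2, n_perm=99, seed=0)
        r_sk, _, _ = sk_mantel(D1, D2, method="pearson", permutations=0)
        assert r == pytest.approx(float(r_sk), abs=1e-10)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            rz.mantel_test(np.zeros((3, 3)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            rz.mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))
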