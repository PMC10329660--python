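import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from geovax.geo_io import DataError, PixelGrid
from geovax.geostat import (
    GpSpec,
    PosteriorDrawCube,
    SizeError,
    ar1_correlation,
    build_model,
    combine_stages,
    fit_posterior,
    matern_covariance,
    predict_surface,
    st_covariance,
)


class TestAr1:
    def test_closed_form_entries(self):
        m = ar1_correlation(0.8, [2000, 2001, 2002])
        assert m[0, 2] == pytest.approx(0.64, abs=1e-12)
        assert m[1, 1] == pytest.approx(1.0, abs=1e-15)

    def test_invalid_rho(self):
        with pytest.raises(DataError):
            ar1_correlation(1.0, [2000, 2001])

    def test_matches_long_series_autocorrelation(self):
        """Sample autocorrelations of a long simulated AR1 series agree with
        the kernel's rho^lag entries within Monte-Carlo error."""
        rho = 0.5
        rng = np.random.default_rng(0)
        n = 400_000
        x = np.empty(n)
        x[0] = rng.normal() / np.sqrt(1 - rho**2)
        innov = rng.normal(size=n) * 1.0
        for t in range(1, n):
            x[t] = rho * x[t - 1] + innov[t]
        x = x / x.std()
        kernel = ar1_correlation(rho, [0, 1, 2, 3])
        for lag in range(1, 4):
            sample_r = float(np.corrcoef(x[:-lag], x[lag:])[0, 1])
            assert sample_r == pytest.approx(kernel[0, lag], abs=0.01)


class TestMatern:
    def test_zero_distance_gives_variance(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        k = matern_covariance(coords, 2.0, 1.7, nu=1.5)
        assert k[0, 0] == pytest.approx(1.7, abs=1e-15)

    def test_nu_three_halves_closed_form(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])
        k = matern_covariance(coords, 1.0, 1.0, nu=1.5)
        expected = (1 + np.sqrt(3)) * np.exp(-np.sqrt(3))
        assert k[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_nu_half_is_exponential_kernel(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(6, 2))
        k = matern_covariance(coords, 2.5, 1.0, nu=0.5)
        from scipy.spatial.distance import cdist

        np.testing.assert_allclose(k, np.exp(-cdist(coords, coords) / 2.5), atol=1e-12)

    def test_unsupported_nu(self):
        with pytest.raises(DataError, match="nu"):
            matern_covariance(np.zeros((2, 2)), 1.0, 1.0, nu=1.0)

    def test_positive_semidefinite_after_jitter(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 20, size=(40, 2))
        k = matern_covariance(coords, 5.0, 2.0, nu=1.5)
        k[np.diag_indices_from(k)] += 1e-8
        assert np.linalg.eigvalsh(k).min() > 0


class TestKronecker:
    def test_identity_product(self):
        out = st_covariance(np.eye(3), np.eye(2))
        np.testing.assert_array_equal(out, np.eye(6))

    def test_eigenvalues_are_pairwise_products(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(4, 4))
        a = a @ a.T
        b = rng.normal(size=(3, 3))
        b = b @ b.T
        joint = st_covariance(a, b)
        expected = np.sort(np.outer(np.linalg.eigvalsh(b), np.linalg.eigvalsh(a)).ravel())
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(joint)), expected, rtol=1e-8)

    def test_psd_closure(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(5, 5))
        a = a @ a.T
        b = rng.normal(size=(4, 4))
        b = b @ b.T
        assert np.linalg.eigvalsh(st_covariance(a, b)).min() >= -1e-8

    def test_dimension_guard(self):
        with pytest.raises(SizeError, match="coarser"):
            st_covariance(np.eye(5000), np.eye(5))


class TestBuildModel:
    def test_degenerate_contract_recovers_first_stacker(self, grid_4x4, toy_obs):
        """With alpha = (1,0,0) and all variance components off, the linear
        predictor equals the logit of the first stacker exactly."""
        obs, stackers = toy_obs
        spec = GpSpec(spatial_range=2.0, spatial_variance=0.0, rho=0.5,
                      nugget_variance=0.0, group_effect_variance=0.0)
        model = build_model(spec, obs, stackers, grid_4x4, [2000])
        eta = model.eta_at_obs(0.0, np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(eta, logit(stackers["c1"].to_numpy()), atol=1e-12)

    def test_misaligned_ids_raise(self, grid_4x4, toy_obs):
        obs, stackers = toy_obs
        bad = stackers.copy()
        bad["observation_id"] = bad["observation_id"] + 100
        spec = GpSpec(spatial_range=2.0)
        with pytest.raises(DataError, match="misaligned"):
            build_model(spec, obs, bad, grid_4x4, [2000])

    def test_log_density_matches_hand_coded_oracle(self, grid_4x4, toy_obs):
        """Joint log density on a 5-observation toy agrees with an explicit
        formula-by-formula reimplementation."""
        obs, stackers = toy_obs
        spec = GpSpec(spatial_range=2.0, spatial_variance=0.6, rho=0.4,
                      nugget_variance=0.2, group_effect_variance=0.3)
        model = build_model(spec, obs, stackers, grid_4x4, [2000])
        rng = np.random.default_rng(8)
        beta0 = 0.3
        alpha = np.array([0.5, 0.3, 0.2])
        gamma = rng.normal(size=2) * 0.4
        u = rng.normal(size=model.n_support) * 0.5
        eps = rng.normal(size=5) * 0.3
        got = model.log_density(beta0, alpha, gamma, u, eps)

        # --- independent oracle: explicit densities, no package internals ---
        from math import lgamma

        s = np.clip(stackers[["c1", "c2", "c3"]].to_numpy(), 1e-4, 1 - 1e-4)
        eta = beta0 + np.log(s / (1 - s)) @ alpha
        group_idx = [0, 0, 1, 1, 1]  # groups sorted: a, b
        centers = grid_4x4.cell_centers()
        # support sites: unique (year, pixel); single year so pixels sorted
        sup_of_obs = {p: i for i, p in enumerate(sorted(obs["pixel_id"]))}
        for i in range(5):
            eta[i] += gamma[group_idx[i]] + u[sup_of_obs[obs["pixel_id"][i]]] + eps[i]
        p = 1 / (1 + np.exp(-eta))
        k, n = obs["successes"].to_numpy(), obs["trials"].to_numpy()
        want = sum(
            lgamma(n[i] + 1) - lgamma(k[i] + 1) - lgamma(n[i] - k[i] + 1)
            + k[i] * np.log(p[i]) + (n[i] - k[i]) * np.log(1 - p[i])
            for i in range(5)
        )
        want += -0.5 * np.log(2 * np.pi * 9.0) - beta0**2 / (2 * 9.0)
        want += sum(
            -0.5 * np.log(2 * np.pi * 0.3) - g**2 / (2 * 0.3) for g in gamma
        )
        want += sum(
            -0.5 * np.log(2 * np.pi * 0.2) - e**2 / (2 * 0.2) for e in eps
        )
        xy = centers[sorted(obs["pixel_id"])]
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        sd3 = np.sqrt(3) * d / 2.0
        kmat = 0.6 * (1 + sd3) * np.exp(-sd3)  # same year: AR1 factor = 1
        kmat[np.diag_indices_from(kmat)] += 1e-10
        sign, logdet = np.linalg.slogdet(kmat)
        want += -0.5 * (
            len(u) * np.log(2 * np.pi) + logdet + u @ np.linalg.solve(kmat, u)
        )
        assert got == pytest.approx(want, abs=1e-8)


@pytest.fixture(scope="module")
def fitted_small_model():
    """Small seeded fit used by several posterior-contract tests."""
    rng = np.random.default_rng(42)
    grid = PixelGrid(8, 8, 2.0)
    years = [2000, 2001]
    n = 120
    pix = rng.integers(0, grid.n_pixels, size=n)
    yr = rng.choice(years, size=n)
    s1 = rng.uniform(0.2, 0.8, n)
    s2 = np.clip(s1 + rng.normal(0, 0.05, n), 0.05, 0.95)
    s3 = rng.uniform(0.3, 0.7, n)
    eta = -0.2 + logit(s1)
    k = rng.binomial(25, expit(eta))
    obs = pd.DataFrame({"observation_id": range(n), "pixel_id": pix, "year": yr,
                        "trials": 25, "successes": k, "group_id": pix % 2})
    stk = pd.DataFrame({"observation_id": range(n), "c1": s1, "c2": s2, "c3": s3})
    spec = GpSpec(spatial_range=5.0, spatial_variance=0.3, rho=0.5,
                  nugget_variance=0.1, group_effect_variance=0.1)
    model = build_model(spec, obs, stk, grid, years)
    fit = fit_posterior(model, 100, seed=9, engine_settings={"n_theta": 10})
    surfaces = np.stack([
        np.full((2, grid.n_pixels), 0.5),
        np.full((2, grid.n_pixels), 0.5),
        np.full((2, grid.n_pixels), 0.5),
    ])
    return model, fit, surfaces


class TestPosterior:
    def test_simplex_constraint_on_weights(self, fitted_small_model):
        _, fit, _ = fitted_small_model
        assert np.all(fit.alpha >= 0)
        np.testing.assert_allclose(fit.alpha.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_reproduces_draws(self, fitted_small_model):
        model, fit, _ = fitted_small_model
        fit2 = fit_posterior(model, 100, seed=9, engine_settings={"n_theta": 10})
        np.testing.assert_array_equal(fit.beta0, fit2.beta0)
        np.testing.assert_array_equal(fit.u_support, fit2.u_support)

    def test_degenerate_fit_matches_ml_oracle(self, grid_4x4):
        """With every variance component off, the posterior for beta0 reduces
        to (weakly penalized) logistic regression with a stacker offset; the
        posterior mean must sit within 2 Monte-Carlo SE of the ML estimate."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 200
        s1 = rng.uniform(0.2, 0.8, n)
        k = rng.binomial(50, expit(-0.4 + logit(s1)))
        obs = pd.DataFrame({"observation_id": range(n),
                            "pixel_id": rng.integers(0, 16, n), "year": 2000,
                            "trials": 50, "successes": k, "group_id": 0})
        stk = pd.DataFrame({"observation_id": range(n), "c1": s1})
        spec = GpSpec(spatial_range=2.0, spatial_variance=0.0, rho=0.5,
                      nugget_variance=0.0, group_effect_variance=0.0)
        model = build_model(spec, obs, stk, grid_4x4, [2000])
        fit = fit_posterior(model, 400, seed=7)
        ml = sm.GLM(
            np.c_[k, 50 - k], np.ones((n, 1)),
            offset=logit(np.clip(s1, 1e-4, 1 - 1e-4)),
            family=sm.families.Binomial(),
        ).fit().params[0]
        mc_se = fit.beta0.std() / np.sqrt(len(fit.beta0))
        assert abs(fit.beta0.mean() - ml) <= 2 * mc_se + 1e-3

    def test_prediction_matches_observed_rate_at_huge_trials(self, grid_4x4):
        """At a data site with enormous trials the posterior mean prediction
        sits within 3 binomial SE of the observed rate."""
        rng = np.random.default_rng(3)
        n_big = 100_000
        p_true = 0.37
        k_big = rng.binomial(n_big, p_true)
        obs = pd.DataFrame({
            "observation_id": [0, 1, 2],
            "pixel_id": [5, 9, 12], "year": 2000,
            "trials": [n_big, 40, 40], "successes": [k_big, 20, 12],
            "group_id": 0,
        })
        stk = pd.DataFrame({"observation_id": [0, 1, 2], "c1": [0.5, 0.5, 0.5]})
        spec = GpSpec(spatial_range=2.0, spatial_variance=0.5, rho=0.5,
                      nugget_variance=0.0, group_effect_variance=0.0,
                      fixed=("rho",))
        model = build_model(spec, obs, stk, grid_4x4, [2000])
        fit = fit_posterior(model, 200, seed=5, engine_settings={"n_theta": 8})
        surfaces = np.full((1, 1, 16), 0.5)
        cube = predict_surface(fit, surfaces, seed=6)
        rate = k_big / n_big
        se = np.sqrt(rate * (1 - rate) / n_big)
        pred = cube.values[:, 0, 5].mean()
        assert abs(pred - rate) <= max(3 * se, 0.01)

    def test_all_prediction_draws_in_unit_interval(self, fitted_small_model):
        model, fit, surfaces = fitted_small_model
        cube = predict_surface(fit, surfaces, seed=1)
        assert cube.values.min() >= 0.0
        assert cube.values.max() <= 1.0

    def test_gp_off_predictions_follow_stackers_exactly(self, grid_4x4):
        """With the GP disabled, predictions are equal wherever the stacker
        surfaces are equal (spatial smoothness is inherited, not added)."""
        rng = np.random.default_rng(4)
        n = 80
        s1 = rng.uniform(0.3, 0.7, n)
        k = rng.binomial(30, s1)
        obs = pd.DataFrame({"observation_id": range(n),
                            "pixel_id": rng.integers(0, 16, n), "year": 2000,
                            "trials": 30, "successes": k, "group_id": 0})
        stk = pd.DataFrame({"observation_id": range(n), "c1": s1})
        spec = GpSpec(spatial_range=2.0, spatial_variance=0.0, rho=0.5,
                      nugget_variance=0.0, group_effect_variance=0.0)
        model = build_model(spec, obs, stk, grid_4x4, [2000])
        fit = fit_posterior(model, 50, seed=8)
        surfaces = np.full((1, 1, 16), 0.42)  # constant stacker surface
        cube = predict_surface(fit, surfaces, seed=9)
        spread = cube.values.max(axis=2) - cube.values.min(axis=2)
        assert spread.max() < 1e-12


class TestCombineStages:
    def _cube(self, grid, values):
        return PosteriorDrawCube(grid=grid, years=[2000], values=values)

    def test_product_composition(self, grid_4x4):
        p1 = self._cube(grid_4x4, np.full((3, 1, 16), 0.5))
        p3c = self._cube(grid_4x4, np.full((3, 1, 16), 0.5))
        p3 = combine_stages(p1, p3c)
        np.testing.assert_allclose(p3.values, 0.25)

    def test_identity_when_conditional_is_one(self, grid_4x4):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.1, 0.9, size=(4, 1, 16))
        p1 = self._cube(grid_4x4, vals)
        p3c = self._cube(grid_4x4, np.ones((4, 1, 16)))
        np.testing.assert_array_equal(combine_stages(p1, p3c).values, vals)

    def test_monotonicity_structural(self, grid_4x4):
        rng = np.random.default_rng(1)
        p1 = self._cube(grid_4x4, rng.uniform(0, 1, size=(10, 1, 16)))
        p3c = self._cube(grid_4x4, rng.uniform(0, 1, size=(10, 1, 16)))
        p3 = combine_stages(p1, p3c)
        assert (p3.values <= p1.values).all()

    def test_inverse_relation_on_state_means(self, grid_4x4):
        """State-mean arithmetic: the implied conditional equals p3/p1; with
        p1 = 51.9% and p3 = 40.0% the implied third-dose completion among
        first-dose recipients is about 77.1%."""
        p1_vals = np.full((5, 1, 16), 0.519)
        p3c_vals = np.full((5, 1, 16), 0.400 / 0.519)
        p1 = self._cube(grid_4x4, p1_vals)
        p3 = combine_stages(p1, self._cube(grid_4x4, p3c_vals))
        implied = p3.values.mean() / p1.values.mean()
        assert implied == pytest.approx(0.771, abs=0.001)
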