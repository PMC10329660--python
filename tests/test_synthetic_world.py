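import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from geovax.geo_io import DataError, PixelGrid
from geovax.synthetic_world import (
    EmptySurveyError,
    SurveyDesign,
    partition_admin,
    simulate_conflict,
    simulate_covariates,
    simulate_gaussian_field,
    simulate_population,
    simulate_survey,
    simulate_truth,
)


class TestGaussianField:
    def test_zero_variance_gives_zero_field(self, grid_4x4):
        field = simulate_gaussian_field(grid_4x4, 2.0, 0.0, seed=0)
        assert not field.any()

    def test_marginal_variance_monte_carlo(self):
        """500 replicate fields on a 10x10 grid: per-pixel sample variance
        stays within [0.85, 1.15] of the nominal unit variance."""
        grid = PixelGrid(10, 10, 1.0)
        rng = np.random.default_rng(6)
        fields = np.stack(
            [simulate_gaussian_field(grid, 3.0, 1.0, rng) for _ in range(500)]
        )
        pixel_var = fields.var(axis=0, ddof=1)
        assert pixel_var.min() > 0.85
        assert pixel_var.max() < 1.15

    def test_same_seed_identical(self, grid_4x4):
        f1 = simulate_gaussian_field(grid_4x4, 2.0, 1.0, seed=7)
        f2 = simulate_gaussian_field(grid_4x4, 2.0, 1.0, seed=7)
        np.testing.assert_array_equal(f1, f2)


class TestCovariates:
    def test_collinear_pair_hits_target_correlation(self):
        grid = PixelGrid(20, 20, 1.0)
        stack = simulate_covariates(
            grid, [2000], 3, seed=1, collinear_pairs=[(0, 1, 0.95)]
        )
        r = np.corrcoef(stack.values[0, 0], stack.values[1, 0])[0, 1]
        assert 0.90 <= r <= 1.00

    def test_single_covariate_stack(self, grid_4x4):
        stack = simulate_covariates(grid_4x4, [2000, 2001], 1, seed=0)
        assert stack.values.shape == (1, 2, 16)

    def test_invalid_target_correlation(self, grid_4x4):
        with pytest.raises(DataError, match="outside"):
            simulate_covariates(grid_4x4, [2000], 2, seed=0,
                                collinear_pairs=[(0, 1, 1.0)])

    def test_same_seed_identical(self, grid_4x4):
        s1 = simulate_covariates(grid_4x4, [2000], 3, seed=5)
        s2 = simulate_covariates(grid_4x4, [2000], 3, seed=5)
        np.testing.assert_array_equal(s1.values, s2.values)


class TestTruth:
    def test_null_model_gives_half_everywhere(self, grid_4x4):
        stack = simulate_covariates(grid_4x4, [2000], 2, seed=0)
        truth = simulate_truth(
            stack, {"p1": np.zeros(3), "p3c": np.zeros(3)},
            {"p1": {"variance": 0.0}, "p3c": {"variance": 0.0}}, rho=0.5, seed=0,
        )
        np.testing.assert_allclose(truth.p1, 0.5)
        np.testing.assert_allclose(truth.p3, 0.25)

    def test_extreme_intercept_drives_p3_to_zero(self, grid_4x4):
        stack = simulate_covariates(grid_4x4, [2000], 2, seed=0)
        b1 = np.array([-30.0, 0.0, 0.0])
        truth = simulate_truth(
            stack, {"p1": b1, "p3c": np.zeros(3)},
            {"p1": {"variance": 0.0}, "p3c": {"variance": 0.0}}, rho=0.5, seed=0,
        )
        assert truth.p3.max() < 1e-10

    def test_known_betas_match_hand_computation(self, grid_4x4):
        stack = simulate_covariates(grid_4x4, [2000], 1, seed=3)
        truth = simulate_truth(
            stack, {"p1": np.array([-0.5, 1.0]), "p3c": np.zeros(2)},
            {"p1": {"variance": 0.0}, "p3c": {"variance": 0.0}}, rho=0.5, seed=0,
        )
        for pix in (0, 7, 13):
            x1 = stack.values[0, 0, pix]
            assert truth.p1[0, pix] == pytest.approx(expit(-0.5 + x1), abs=1e-12)

    def test_dose_ordering_holds_everywhere(self):
        grid = PixelGrid(8, 8, 1.0)
        stack = simulate_covariates(grid, [2000, 2001], 3, seed=9)
        truth = simulate_truth(
            stack,
            {"p1": np.array([0.2, 0.5, -0.3, 0.0]), "p3c": np.array([-0.1, 0.4, 0.0, 0.2])},
            {"p1": {"variance": 0.5, "spatial_range": 3.0},
             "p3c": {"variance": 0.5, "spatial_range": 3.0}},
            rho=0.7, seed=4,
        )
        assert (truth.p3 <= truth.p1 + 1e-15).all()


class TestPartition:
    def test_four_lgas_of_nine_pixels(self):
        grid = PixelGrid(6, 6, 1.0)
        admin = partition_admin(grid, 1, 4)
        sizes = sorted(len(admin.pixels_of(u)) for u in admin.lga_ids)
        assert sizes == [9, 9, 9, 9]

    def test_single_unit_covers_grid(self, grid_4x4):
        admin = partition_admin(grid_4x4, 1, 1)
        assert len(admin.pixels_of(admin.lga_ids[0])) == 16

    def test_borno_like_shape(self):
        grid = PixelGrid(30, 30, 1.0)
        admin = partition_admin(grid, 3, 9)
        assert len(admin.lga_ids) == 27
        parents = {admin.parent_of(u) for u in admin.lga_ids}
        assert parents == set(admin.state_ids)
        # partition property: unit pixel counts sum to the grid size
        assert sum(len(admin.pixels_of(u)) for u in admin.lga_ids) == 900


class TestPopulation:
    def test_no_centers_is_uniform_and_conserved(self, grid_4x4):
        pop = simulate_population(grid_4x4, 0, 1000.0, seed=0)
        assert pop.sum() == pytest.approx(1000.0, abs=1e-6)
        assert pop.std() < 1e-9

    def test_single_center_pixel_is_maximum(self):
        grid = PixelGrid(9, 9, 1.0)
        rng = np.random.default_rng(3)
        idx = np.random.default_rng(3).choice(grid.n_pixels, size=1, replace=False)
        pop = simulate_population(grid, 1, 1000.0, seed=3)
        assert pop.argmax() == idx[0]

    def test_mass_conservation(self):
        grid = PixelGrid(12, 12, 1.0)
        pop = simulate_population(grid, 3, 123_456.0, seed=1)
        assert pop.sum() == pytest.approx(123_456.0, abs=1.0)
        assert (pop >= 0).all()


class TestConflict:
    def test_zero_rate_empty_table(self, borno_like):
        _, admin, _ = borno_like
        events = simulate_conflict(admin, admin.lga_ids[:5], 0.0, 5.0, [2016], seed=0)
        assert events.empty

    def test_events_contained_in_generating_lga(self, borno_like):
        grid, admin, _ = borno_like
        events = simulate_conflict(admin, admin.lga_ids, 5.0, 5.0, [2016], seed=2)
        pix = grid.pixel_of_xy(events["x"].to_numpy(), events["y"].to_numpy())
        assert (admin.pixel_owner[pix] == events["lga_id"].to_numpy()).all()

    def test_poisson_total_within_three_sigma(self, borno_like):
        _, admin, _ = borno_like
        affected = admin.lga_ids[:24]
        events = simulate_conflict(admin, affected, 10.0, 5.0, [2016], seed=5)
        expected = 240.0
        assert abs(len(events) - expected) <= 3 * np.sqrt(expected)


class TestSurvey:
    @pytest.fixture
    def world(self, borno_like):
        grid, admin, population = borno_like
        stack = simulate_covariates(grid, list(range(2013, 2017)), 3, seed=21)
        truth = simulate_truth(
            stack,
            {"p1": np.array([-0.2, 0.8, -0.5, 0.0]), "p3c": np.array([0.3, 0.5, 0.0, 0.0])},
            {"p1": {"variance": 0.3}, "p3c": {"variance": 0.2}},
            rho=0.7, seed=22,
        )
        return grid, admin, population, truth

    def test_total_dropout_gives_empty_survey_error(self, world):
        grid, admin, population, truth = world
        design = SurveyDesign(n_clusters=50, survey_year=2017, conflict_dropout_prob=1.0)
        with pytest.raises(EmptySurveyError):
            simulate_survey(truth, population, admin, design, admin.lga_ids, seed=0)

    def test_conflict_dropout_replicates_six_sampled_lgas(self, world):
        """Dropping 21 of 27 conflict-affected LGAs leaves 6 sampled, the
        pattern observed in the 2016-17 survey round."""
        grid, admin, population, truth = world
        design = SurveyDesign(n_clusters=800, survey_year=2017, conflict_dropout_prob=1.0)
        conflict = admin.lga_ids[:21]
        uniform_pop = np.full(grid.n_pixels, 100.0)
        survey = simulate_survey(truth, uniform_pop, admin, design, conflict, seed=1)
        sampled = set(survey["lga_id"])
        assert sampled == set(admin.lga_ids[21:])
        assert len(sampled) == 6

    def test_binomial_nesting(self, world):
        grid, admin, population, truth = world
        design = SurveyDesign(n_clusters=100, survey_year=2017, conflict_dropout_prob=0.0)
        survey = simulate_survey(truth, population, admin, design, [], seed=3)
        assert (survey["k3"] <= survey["k1"]).all()
        assert (survey["k1"] <= survey["N"]).all()

    def test_huge_sample_recovers_truth(self, world):
        """With ~10^5 children per cluster and no dropout the tabulated rates
        sit within 3 binomial standard errors of the latent truth."""
        grid, admin, population, truth = world
        design = SurveyDesign(
            n_clusters=10, children_per_cluster=100_000, survey_year=2017,
            conflict_dropout_prob=0.0,
        )
        survey = simulate_survey(truth, population, admin, design, [], seed=4)
        for _, row in survey.iterrows():
            p1 = truth.at(row["pixel_id"], row["cohort_year"], "p1")[0]
            p3 = truth.at(row["pixel_id"], row["cohort_year"], "p3")[0]
            se1 = np.sqrt(p1 * (1 - p1) / row["N"])
            se3 = np.sqrt(p3 * (1 - p3) / row["N"])
            assert abs(row["k1"] / row["N"] - p1) <= 3 * se1 + 1e-9
            assert abs(row["k3"] / row["N"] - p3) <= 3 * se3 + 1e-9
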