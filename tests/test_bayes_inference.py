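"""Likelihood, prior, posterior and the posterior-mean estimator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from octbayes import (
    GridSpec,
    PriorSpec,
    dr_estimate,
    estimate_map,
    likelihood,
    likelihood_multi,
    mean_signal,
    posterior,
    posterior_map,
    posterior_mean,
    posterior_variance,
    prior_density,
    sample_prior_map,
    speckle_sample,
)
from octbayes.dr_recovery import DRMap

from conftest import count_local_maxima, importance_sampling_moments

FIG1_PRIOR = PriorSpec(layer_mean=0.4, zeta=6.87e-2)


class TestLikelihood:
    def test_point_values(self):
        assert likelihood(2.0, 2.0) == pytest.approx(0.5 * math.exp(-1), rel=1e-12)
        assert likelihood(2.0, 2.0) == pytest.approx(0.18394, abs=1e-5)
        assert likelihood(0.0, 4.0) == pytest.approx(0.25)

    @pytest.mark.parametrize("mu", [0.5, 2.0, 4.0])
    def test_normalizes_over_estimates(self, mu):
        total, _ = integrate.quad(lambda x: likelihood(x, mu), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            likelihood(1.0, 0.0)
        with pytest.raises(ValueError):
            likelihood(-1.0, 1.0)


class TestLikelihoodMulti:
    def test_single_estimate_reduces_to_likelihood(self):
        assert likelihood_multi([1.7], 2.3) == pytest.approx(likelihood(1.7, 2.3), rel=1e-14)

    def test_three_estimate_value(self):
        assert likelihood_multi([1.0, 2.0, 3.0], 2.0) == pytest.approx(
            (1 / 8) * math.exp(-3), rel=1e-12
        )
        assert likelihood_multi([1.0, 2.0, 3.0], 2.0) == pytest.approx(6.2234e-3, abs=1e-6)

    @given(
        k=st.integers(1, 6),
        mu=st.floats(0.2, 5.0),
        data=st.data(),
    )
    @settings(max_examples=30, deadline=None)
    def test_log_joint_is_sum_of_log_singles(self, k, mu, data):
        mu_hats = [data.draw(st.floats(0.0, 10.0)) for _ in range(k)]
        log_joint = math.log(likelihood_multi(mu_hats, mu))
        log_sum = sum(math.log(likelihood(m, mu)) for m in mu_hats)
        assert log_joint == pytest.approx(log_sum, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            likelihood_multi([], 2.0)


class TestPriorDensity:
    def test_value_at_mode(self):
        expected = 1 / math.sqrt(2 * math.pi * 0.4 * 6.87e-2)
        assert prior_density(0.4, FIG1_PRIOR) == pytest.approx(expected, rel=1e-12)
        assert prior_density(0.4, FIG1_PRIOR) == pytest.approx(2.4066, abs=1e-4)

    def test_symmetry_about_layer_mean(self):
        for d in (0.05, 0.13, 0.4):
            assert prior_density(0.4 + d, FIG1_PRIOR) == pytest.approx(
                prior_density(0.4 - d, FIG1_PRIOR), rel=1e-12
            )

    def test_unit_mass_and_negligible_truncation(self):
        prior = PriorSpec(2.0, 1e-2)  # layer_mean = 14 prior sd
        total, _ = integrate.quad(lambda x: prior_density(x, prior), -np.inf, np.inf)
        positive, _ = integrate.quad(lambda x: prior_density(x, prior), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert positive == pytest.approx(1.0, abs=1e-6)

    def test_warns_when_truncation_mass_is_large(self):
        wide = PriorSpec(0.5, 1.0)  # sd sqrt(0.5) > mean
        with pytest.warns(RuntimeWarning, match="prior mass below zero"):
            prior_density(0.5, wide)


class TestPosterior:
    @given(
        layer_mean=st.floats(0.2, 5.0),
        zeta=st.floats(1e-3, 1e-1),
        frac=st.floats(0.0, 3.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_normalized_on_grid(self, layer_mean, zeta, frac):
        prior = PriorSpec(layer_mean, zeta)
        post = posterior([frac * layer_mean], prior)
        assert np.trapezoid(post.density, post.mu_grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(post.density >= 0)

    def test_all_zero_estimates_warn(self):
        with pytest.warns(RuntimeWarning, match="non-integrable"):
            posterior([0.0], FIG1_PRIOR)

    def test_unimodal_for_moderate_estimate(self):
        post = posterior([1.3], FIG1_PRIOR)
        assert count_local_maxima(post.density) == 1

    def test_bimodal_for_small_estimate(self):
        post = posterior([0.015], FIG1_PRIOR)
        assert count_local_maxima(post.density) == 2


class TestPosteriorSummaries:
    def test_point_mass_prior_pins_the_mean(self):
        # with zeta -> 0 the prior is far narrower than the grid spacing, so
        # the mean is pinned to within one quadrature cell of the layer mean
        prior = PriorSpec(2.0, 1e-8)
        for mu_hat in (0.1, 2.0, 6.0):
            post = posterior([mu_hat], prior)
            assert posterior_mean(post) == pytest.approx(2.0, abs=0.02)
            assert posterior_variance(post) < 1e-3

    def test_mean_strictly_inside_grid(self):
        post = posterior([1.0], FIG1_PRIOR)
        m = posterior_mean(post)
        assert post.mu_grid[0] < m < post.mu_grid[-1]

    def test_variance_non_negative(self):
        for mu_hat in (0.0001, 0.5, 3.0):
            assert posterior_variance(posterior([mu_hat], FIG1_PRIOR)) >= 0

    def test_map_of_symmetric_unimodal_density_is_the_mode(self):
        prior = PriorSpec(3.0, 1e-4)  # prior dominates; posterior ~ Gaussian
        post = posterior([3.0], prior)
        i = int(np.argmax(post.density))
        spacing = post.mu_grid[i + 1] - post.mu_grid[i]
        # the quadratically refined MaP sits within one grid cell of the mode
        assert abs(posterior_map(post) - post.mu_grid[i]) < spacing

    @given(mu_hat=st.floats(0.001, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_mean_monotone_in_estimate(self, mu_hat):
        """A larger observed DR estimate never lowers the inferred mean."""
        grid = GridSpec(mu_hi=20.0)  # shared grid so comparisons are exact
        m1 = posterior_mean(posterior([mu_hat], FIG1_PRIOR, grid))
        m2 = posterior_mean(posterior([mu_hat * 1.1 + 0.01], FIG1_PRIOR, grid))
        assert m2 >= m1 - 1e-9

    def test_moments_match_importance_sampling_oracle(self):
        """Quadrature vs brute-force IS on a small randomized sweep."""
        rng = np.random.default_rng(2024)
        for i in range(8):
            layer_mean = rng.uniform(0.2, 5.0)
            zeta = 10 ** rng.uniform(-3, -1)
            mu_hat = rng.uniform(0.0, 3 * layer_mean)
            prior = PriorSpec(layer_mean, zeta)
            post = posterior([mu_hat], prior)
            oracle = importance_sampling_moments([mu_hat], prior, 200_000, seed=100 + i)
            assert abs(posterior_mean(post) - oracle["mean"]) < 4 * oracle["se_mean"]
            assert abs(posterior_variance(post) - oracle["var"]) < 4 * oracle["se_var"]

    def test_consistency_with_growing_scan_count(self):
        """With k i.i.d. estimates the posterior mean concentrates on the
        truth: mean absolute error shrinks monotonically over k=1,10,100."""
        mu_true = 2.0
        prior = PriorSpec(1.5, 5e-2)  # deliberately off-center prior
        rng = np.random.default_rng(17)
        errors = []
        for k in (1, 10, 100):
            err = [
                abs(
                    posterior_mean(
                        posterior(rng.exponential(mu_true, size=k), prior, GridSpec(n_points=1024))
                    )
                    - mu_true
                )
                for _ in range(200)
            ]
            errors.append(np.mean(err))
        assert errors[0] > errors[1] > errors[2]


class TestEstimateMap:
    def _dr_from_values(self, values, geometry=None):
        values = np.asarray(values, dtype=float)
        mask = np.ones_like(values, dtype=bool)
        mask[-1:] = False
        return DRMap(values, mask, 0.0, geometry)

    def test_matches_voxelwise_posterior_mean(self):
        """The vectorized map agrees with the one-voxel reference path."""
        prior = PriorSpec(1.2, 3e-2)
        values = np.array([[0.3, 1.2], [2.7, 0.01], [0.0, 0.0]])
        dr = self._dr_from_values(values)
        out = estimate_map(dr, prior)
        for idx in np.argwhere(dr.admissible_mask):
            ref = posterior_mean(posterior([values[tuple(idx)]], prior))
            assert out[tuple(idx)] == pytest.approx(ref, rel=1e-6)

    def test_masked_voxels_are_nan(self):
        dr = self._dr_from_values(np.ones((4, 3)))
        out = estimate_map(dr, PriorSpec(1.0, 1e-2))
        assert np.all(np.isnan(out[-1]))
        assert np.all(np.isfinite(out[:-1]))

    def test_tiny_zeta_returns_layer_mean_everywhere(self):
        dr = self._dr_from_values(np.full((5, 4), 2.0))
        out = estimate_map(dr, PriorSpec(2.0, 1e-10))
        # point-mass prior: pinned within one quadrature cell of 2.0
        np.testing.assert_allclose(out[:-1], 2.0, atol=0.02)

    def test_permutation_equivariant_across_a_lines(self):
        rng = np.random.default_rng(5)
        values = rng.exponential(1.0, size=(6, 5))
        prior = PriorSpec(1.0, 2e-2)
        out = estimate_map(self._dr_from_values(values), prior)
        perm = [3, 1, 4, 0, 2]
        out_perm = estimate_map(self._dr_from_values(values[:, perm]), prior)
        np.testing.assert_allclose(out_perm, out[:, perm], rtol=1e-12, equal_nan=True)

    def test_posterior_map_beats_raw_dr_on_homogeneous_scan(self, fig4_geometry):
        """Voxelwise RMSE of the posterior-mean map is below that of the raw
        DR estimates for a homogeneous speckled B-scan."""
        from octbayes.cli_workflows import constant_profile
        from octbayes.dr_recovery import layer_mean as lm

        mu_true = 2.0
        scan = speckle_sample(mean_signal(constant_profile(fig4_geometry, mu_true, 30)), 13)
        dr = dr_estimate(scan)
        prior = PriorSpec(lm(dr), 5e-2)
        post_map = estimate_map(dr, prior)
        mask = dr.admissible_mask
        rmse_dr = np.sqrt(np.mean((dr.estimates[mask] - mu_true) ** 2))
        rmse_post = np.sqrt(np.mean((post_map.values[mask] - mu_true) ** 2))
        assert rmse_post < rmse_dr

    def test_prior_sampled_truth_round_trip(self, small_geometry):
        """End-to-end: truth from the prior, speckled scan, DR, posterior map."""
        prior = PriorSpec(2.0, 5e-2)
        truth = sample_prior_map(prior, small_geometry, seed=21, n_lateral=10)
        scan = speckle_sample(mean_signal(truth), seed=22)
        dr = dr_estimate(scan)
        from octbayes.dr_recovery import layer_mean as lm

        post_map = estimate_map(dr, PriorSpec(lm(dr), prior.zeta))
        mask = dr.admissible_mask
        err_dr = np.abs(dr.estimates[mask] - truth.values[mask]).mean()
        err_post = np.abs(post_map.values[mask] - truth.values[mask]).mean()
        assert err_post < err_dr
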