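"""Likelihood, posterior, Bayesian estimate and response scaling."""

import numpy as np
import pytest

import headingbayes as hb
from headingbayes.angles import circular_integral

# Reference value computed with an independent brute-force implementation
# of the full chain (prior, trapezoid cumulative mapping, von Mises
# likelihood, pointwise Bayes, circular mean) on a 2^16-point grid.
ORACLE_ESTIMATE_TWO_PEAK_K2_AT_10DEG = 11.73505  # degrees


class TestLikelihood:
    def test_small_kappa_approaches_uniform(self, default_mapping):
        lik = hb.likelihood(0.3, default_mapping, hb.ObserverParams(1e-8))
        assert np.allclose(lik, 1.0 / (2 * np.pi), atol=1e-9)

    def test_mode_at_true_heading(self, default_mapping, default_prior):
        theta0 = np.deg2rad(21.0)
        m = float(default_mapping.forward(theta0))
        lik = hb.likelihood(m, default_mapping, hb.ObserverParams(4.0))
        peak = default_prior.grid[np.argmax(lik)]
        assert peak == pytest.approx(theta0, abs=2 * np.pi / default_prior.resolution)

    @pytest.mark.parametrize("kappa", [0.5, 2.0, 16.0])
    @pytest.mark.parametrize("theta0_deg", [0.0, 21.0, -33.0])
    def test_unit_mass_over_measurements(self, default_mapping, kappa, theta0_deg):
        # at fixed theta, p(m|theta) is a von Mises density in m
        m_grid = -np.pi + 2 * np.pi * np.arange(2048) / 2048
        theta = np.deg2rad(theta0_deg)
        ftil = float(default_mapping.forward(theta))
        params = hb.ObserverParams(kappa)
        vals = np.array(
            [hb.likelihood(m, default_mapping, params,
                           theta_grid=np.array([theta]))[0] for m in m_grid]
        )
        assert circular_integral(vals, m_grid) == pytest.approx(1.0, abs=1e-8)
        assert m_grid[np.argmax(vals)] == pytest.approx(ftil, abs=2 * np.pi / 2048)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            hb.ObserverParams(0.0)
        with pytest.raises(ValueError, match="kappa"):
            hb.ObserverParams(-3.0)


class TestPosterior:
    def test_uniform_prior_posterior_proportional_to_likelihood(
        self, flat_prior, flat_mapping
    ):
        params = hb.ObserverParams(3.0)
        m = 0.4
        post = hb.posterior(m, flat_mapping, flat_prior, params)
        lik = hb.likelihood(m, flat_mapping, params)
        lik = lik / circular_integral(lik, flat_prior.grid)
        assert np.allclose(post, lik, atol=1e-10)

    @pytest.mark.parametrize("m", [-2.0, 0.0, 1.3])
    @pytest.mark.parametrize("kappa", [0.3, 4.0, 100.0])
    def test_unit_mass(self, default_prior, default_mapping, m, kappa):
        post = hb.posterior(m, default_mapping, default_prior, hb.ObserverParams(kappa))
        assert circular_integral(post, default_prior.grid) == pytest.approx(1.0, abs=1e-8)

    def test_concentrates_near_zero_for_large_kappa(self, default_prior, default_mapping):
        # brute-force check on the coincident nodes of a 10x finer grid
        post = hb.posterior(0.0, default_mapping, default_prior, hb.ObserverParams(50.0))
        near = np.abs(default_prior.grid) < np.deg2rad(15.0)
        mass = float(post[near].sum() * 2 * np.pi / len(default_prior.grid))
        assert mass > 0.99

        fine_prior = default_prior.with_resolution(10 * default_prior.resolution)
        fine_mapping = hb.encode(fine_prior)
        fine_post = hb.posterior(0.0, fine_mapping, fine_prior, hb.ObserverParams(50.0))
        # every coarse node coincides with a fine node
        assert np.allclose(fine_prior.grid[::10], default_prior.grid, atol=1e-12)
        assert np.allclose(fine_post[::10], post, atol=1e-4)
        assert np.max(np.abs(fine_post[::10] - post)) / fine_post.max() < 1e-5


class TestEstimate:
    def test_uniform_prior_estimate_is_unbiased(self, flat_prior, flat_mapping):
        for theta0_deg in (-33.0, -9.0, 0.0, 15.0, 33.0):
            m = float(flat_mapping.forward(np.deg2rad(theta0_deg)))
            est = hb.estimate(m, flat_mapping, flat_prior, hb.ObserverParams(2.0))
            assert est == pytest.approx(theta0_deg, abs=1e-6)

    def test_symmetric_prior_estimate_at_zero(self, default_prior, default_mapping):
        est = hb.estimate(0.0, default_mapping, default_prior, hb.ObserverParams(2.0))
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, default_prior, default_mapping):
        m = float(default_mapping.forward(np.deg2rad(10.0)))
        est = hb.estimate(m, default_mapping, default_prior, hb.ObserverParams(2.0))
        assert est == pytest.approx(ORACLE_ESTIMATE_TWO_PEAK_K2_AT_10DEG, abs=0.01)
        # repulsion away from the straight-ahead prior peak: the efficient
        # encoding makes the likelihood asymmetric and pushes the estimate
        # beyond the true 10 deg
        assert est > 10.0

    def test_monotone_in_measurement(self, default_prior, default_mapping):
        params = hb.ObserverParams(2.0)
        ms = np.linspace(-2.5, 2.5, 41)
        ests = [hb.estimate(float(m), default_mapping, default_prior, params) for m in ms]
        assert np.all(np.diff(ests) > 0)


class TestResponseScaling:
    def test_identity_alpha(self):
        cond = hb.standard_condition("arc240")
        rm = hb.ResponseMapping({"arc240": 1.0})
        assert hb.apply_response_mapping(17.0, cond, rm) == pytest.approx(17.0)

    @pytest.mark.parametrize("alpha,theta,expected", [
        (1.2, 10.0, 12.0),
        (0.8, -30.0, -24.0),
    ])
    def test_scaling_arithmetic(self, alpha, theta, expected):
        cond = hb.standard_condition("arc240")
        rm = hb.ResponseMapping({"arc240": alpha})
        assert hb.apply_response_mapping(theta, cond, rm) == pytest.approx(expected)

    def test_clipping_at_probe_edge(self):
        cond = hb.standard_condition("arc80")
        rm = hb.ResponseMapping({"arc80": 1.5})
        assert hb.apply_response_mapping(35.0, cond, rm) == pytest.approx(40.0)
        assert hb.apply_response_mapping(-35.0, cond, rm) == pytest.approx(-40.0)

    def test_full_circle_wraps_instead_of_clipping(self):
        cond = hb.standard_condition("circle360")
        rm = hb.ResponseMapping({"circle360": 1.5})
        assert hb.apply_response_mapping(150.0, cond, rm) == pytest.approx(-135.0)

    def test_missing_condition_named_in_error(self):
        rm = hb.ResponseMapping({"arc80": 1.0})
        with pytest.raises(KeyError, match="arc240"):
            rm.alpha_for("arc240")

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            hb.ResponseMapping({"arc80": 0.0})
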