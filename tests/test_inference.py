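"""Likelihood evaluation and maximum-likelihood parameter fitting."""

import numpy as np
import pandas as pd
import pytest

import headingbayes as hb
from headingbayes import Block, CONSTANT_SPEED, ExperimentDesign


@pytest.fixture(scope="module")
def exp3_setup(fit_prior, exp3_alphas):
    return {
        "prior": fit_prior,
        "params": hb.ObserverParams(4.0),
        "rm": hb.ResponseMapping(exp3_alphas),
    }


class TestNLL:
    def test_additive_over_disjoint_trial_sets(self, exp3_trials, exp3_setup):
        s = exp3_setup
        half_a = exp3_trials.iloc[:270]
        half_b = exp3_trials.iloc[270:]
        total = hb.negative_log_likelihood(exp3_trials, s["prior"], s["params"], s["rm"])
        parts = hb.negative_log_likelihood(half_a, s["prior"], s["params"], s["rm"]) + \
            hb.negative_log_likelihood(half_b, s["prior"], s["params"], s["rm"])
        assert total == pytest.approx(parts, abs=1e-8)

    def test_report_at_mode_beats_report_far_away(self, exp3_setup):
        s = exp3_setup
        mapping = hb.encode(s["prior"])
        rd = hb.response_density(
            21.0, hb.standard_condition("arc160"), s["prior"], mapping,
            s["params"], s["rm"],
        )
        mode = float(rd.r_deg[np.argmax(rd.pdf_deg)])

        def one_trial_nll(report):
            trial = pd.DataFrame({
                "condition_label": ["arc160"],
                "true_heading_deg": [21.0],
                "reported_heading_deg": [report],
            })
            return hb.negative_log_likelihood(trial, s["prior"], s["params"], s["rm"])

        assert one_trial_nll(mode) < one_trial_nll(mode - 20.0)

    def test_generating_parameters_beat_shuffled_alphas(self, fit_prior):
        # data simulated with increasing alphas must be more likely under
        # the generating mapping than under the reversed one
        design = hb.make_design("exp3")
        true_rm = hb.ResponseMapping({"arc80": 0.85, "arc160": 1.0, "arc240": 1.15})
        flip_rm = hb.ResponseMapping({"arc80": 1.15, "arc160": 1.0, "arc240": 0.85})
        params = hb.ObserverParams(4.0)
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            trials = hb.generate_trials(design, fit_prior, params, true_rm,
                                        seed=seed, n_participants=1)
            nll_true = hb.negative_log_likelihood(trials, fit_prior, params, true_rm)
            nll_flip = hb.negative_log_likelihood(trials, fit_prior, params, flip_rm)
            wins += nll_true < nll_flip
        assert wins >= int(0.95 * n_rep)

    def test_missing_condition_error_names_it(self, exp3_trials, exp3_setup):
        s = exp3_setup
        bad_rm = hb.ResponseMapping({"arc80": 1.0, "arc160": 1.0})
        with pytest.raises(KeyError, match="arc240"):
            hb.negative_log_likelihood(exp3_trials, s["prior"], s["params"], bad_rm)

    def test_empty_table_rejected(self, exp3_setup):
        s = exp3_setup
        empty = pd.DataFrame(columns=["condition_label", "true_heading_deg",
                                      "reported_heading_deg"])
        with pytest.raises(ValueError, match="empty"):
            hb.negative_log_likelihood(empty, s["prior"], s["params"], s["rm"])


class TestFitMLE:
    def test_fit_is_deterministic(self, exp3_trials, fit_prior):
        a = hb.fit_mle(exp3_trials, fit_prior, seed=5, n_restarts=2)
        b = hb.fit_mle(exp3_trials, fit_prior, seed=5, n_restarts=2)
        assert a == b

    def test_restart_optima_agree(self, exp3_trials, fit_prior):
        fit = hb.fit_mle(exp3_trials, fit_prior, seed=1, n_restarts=5)
        assert max(fit.start_nlls) - min(fit.start_nlls) < 1e-3
        assert fit.converged
        assert fit.nll <= min(fit.start_nlls) + 1e-12

    def test_uniform_prior_alpha_recovery(self, flat_prior):
        # alpha = 1 data fitted with the matched (flat) prior
        design = hb.make_design("exp3")
        rm = hb.ResponseMapping({"arc80": 1.0, "arc160": 1.0, "arc240": 1.0})
        prior = flat_prior.with_resolution(512)
        trials = hb.generate_trials(design, prior, hb.ObserverParams(4.0), rm,
                                    seed=0, n_participants=1)
        fit = hb.fit_mle(trials, prior, seed=0, n_restarts=3)
        for alpha in fit.alpha_hats.values():
            assert 0.9 <= alpha <= 1.1

    def test_circle_alpha_constraint(self, fit_prior):
        design = hb.make_design("exp2", n_participants=1)
        rm = hb.ResponseMapping({"line80": 0.9, "arc80": 0.9, "circle360": 1.0})
        trials = hb.generate_trials(design, fit_prior, hb.ObserverParams(4.0), rm,
                                    seed=1, n_participants=1)
        free = hb.fit_mle(trials, fit_prior, seed=1, n_restarts=2)
        pinned = hb.fit_mle(trials, fit_prior, seed=1, n_restarts=2,
                            constrain_circle_alpha=True)
        assert pinned.alpha_hats["circle360"] == 1.0
        # generating alpha was 1, so the constraint costs essentially nothing
        assert pinned.nll <= free.nll + 2.0


class TestRecoveryStudy:
    def test_zero_noise_proxy_recovers_alphas_tightly(self, fit_prior):
        # kappa = 100, ~2000 trials: alphas pinned down to < 0.02
        blocks = tuple(
            Block(hb.standard_condition(lb), CONSTANT_SPEED, 56)
            for lb in ("arc80", "arc160", "arc240")
        )
        design = ExperimentDesign("custom", blocks=blocks, n_participants=1,
                                  interleaved=True)
        alphas = {"arc80": 0.85, "arc160": 1.0, "arc240": 1.15}
        report = hb.recovery_study(
            [(100.0, alphas)], design, fit_prior, n_replicates=2, seed=9,
            n_restarts=2,
        )
        assert len(report) == 3  # |grid| x conditions
        assert list(report.columns) == [
            "kappa_true", "alpha_true", "condition", "kappa_hat_mean",
            "kappa_hat_sd", "alpha_hat_mean", "alpha_hat_sd", "n_replicates",
        ]
        for _, row in report.iterrows():
            assert abs(row.alpha_hat_mean - alphas[row.condition]) < 0.02
            assert row.alpha_hat_sd < 0.02

    def test_alpha_sd_shrinks_with_sample_size(self, fit_prior):
        # doubling the trial count halves the alpha SD within a factor 1.5
        alphas = {"arc160": 1.0}

        def run(reps, seed):
            blocks = (Block(hb.standard_condition("arc160"), CONSTANT_SPEED, reps),)
            design = ExperimentDesign("custom", blocks=blocks, n_participants=1,
                                      interleaved=True)
            return hb.recovery_study(
                [(100.0, alphas)], design, fit_prior, n_replicates=8, seed=seed,
                n_restarts=2,
            ).alpha_hat_sd.iloc[0]

        sd_small = run(5, 21)
        sd_large = run(10, 21)
        ratio = sd_small / sd_large
        assert np.sqrt(2.0) / 1.5 < ratio < np.sqrt(2.0) * 1.5
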