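"""Experiment designs, trial generation, stimulus kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import headingbayes as hb
from headingbayes import Block, CONSTANT_SPEED, ExperimentDesign, SpeedProfile

from conftest import right_continuous_ecdf_distance


class TestDesigns:
    def test_heading_set_is_the_twelve_standard_directions(self):
        expected = {-33, -27, -21, -15, -9, -3, 3, 9, 15, 21, 27, 33}
        for exp_id in ("exp1", "exp2", "exp3"):
            design = hb.make_design(exp_id)
            assert set(design.heading_set_deg) == expected

    def test_exp1_block_sizes(self):
        design = hb.make_design("exp1")
        nh = len(design.heading_set_deg)
        line_blocks = [b for b in design.blocks if b.condition.label == "line80"]
        circle_blocks = [b for b in design.blocks if b.condition.label == "circle360"]
        assert [b.n_trials(nh) for b in line_blocks] == [480, 480]
        assert [b.n_trials(nh) for b in circle_blocks] == [180, 180]
        # each group runs one constant- and one triangular-speed block
        assert {b.speed_profile.kind for b in line_blocks} == {"constant", "triangular"}

    def test_exp2_block_size(self):
        design = hb.make_design("exp2")
        nh = len(design.heading_set_deg)
        assert all(b.n_trials(nh) == 240 for b in design.blocks)
        assert [b.condition.label for b in design.blocks] == [
            "line80", "arc80", "circle360"
        ]

    def test_exp3_totals_540_and_720(self):
        assert hb.make_design("exp3").n_trials_per_participant() == 540
        assert hb.make_design(
            "exp3", exp3_reps_per_heading=20
        ).n_trials_per_participant() == 720

    def test_unknown_experiment_lists_valid_ids(self):
        with pytest.raises(ValueError, match="exp1.*exp2.*exp3"):
            hb.make_design("exp9")


class TestGeneration:
    def test_schedule_exactness(self, exp3_trials, exp3_design):
        counts = exp3_trials.groupby(
            ["condition_label", "true_heading_deg"]
        ).size()
        assert (counts == 15).all()
        assert len(counts) == 36
        assert len(exp3_trials) == 540

    def test_determinism_contract(self, exp3_design, fit_prior, exp3_alphas):
        params = hb.ObserverParams(4.0)
        rm = hb.ResponseMapping(exp3_alphas)
        a = hb.generate_trials(exp3_design, fit_prior, params, rm, seed=7, n_participants=1)
        b = hb.generate_trials(exp3_design, fit_prior, params, rm, seed=7, n_participants=1)
        c = hb.generate_trials(exp3_design, fit_prior, params, rm, seed=8, n_participants=1)
        assert a.equals(b)
        # the (heading, condition) schedule belongs to the design, not the draw
        assert a["true_heading_deg"].equals(c["true_heading_deg"])
        assert a["condition_label"].equals(c["condition_label"])
        assert (a["reported_heading_deg"] != c["reported_heading_deg"]).any()

    def test_reports_stay_inside_probe(self, exp3_trials):
        for label, half in (("arc80", 40.0), ("arc160", 80.0), ("arc240", 120.0)):
            sub = exp3_trials[exp3_trials.condition_label == label]
            assert (sub.reported_heading_deg.abs() <= half + 1e-9).all()

    def test_noiseless_limit_reproduces_true_headings(self):
        prior = hb.uniform_prior(4096)
        design = hb.make_design("exp3")
        rm = hb.ResponseMapping({"arc80": 1.0, "arc160": 1.0, "arc240": 1.0})
        trials = hb.generate_trials(
            design, prior, hb.ObserverParams(1e5), rm, seed=2, n_participants=1
        )
        err = np.abs(trials.reported_heading_deg - trials.true_heading_deg)
        assert err.max() < 1.0

    def test_empirical_distribution_matches_response_density(
        self, default_prior, default_mapping
    ):
        params = hb.ObserverParams(4.0)
        rm = hb.ResponseMapping({"arc160": 1.15})
        cond = hb.standard_condition("arc160")
        design = ExperimentDesign(
            "cell",
            heading_set_deg=(21.0,),
            blocks=(Block(cond, CONSTANT_SPEED, 10_000),),
            n_participants=1,
        )
        trials = hb.generate_trials(design, default_prior, params, rm, seed=4,
                                    n_participants=1)
        rd = hb.response_density(21.0, cond, default_prior, default_mapping, params, rm)
        d = right_continuous_ecdf_distance(
            trials.reported_heading_deg.to_numpy(), rd
        )
        assert d < 0.02

    def test_participant_heterogeneity_only_with_multiple_participants(
        self, fit_prior, exp3_design, exp3_alphas
    ):
        params = hb.ObserverParams(4.0)
        rm = hb.ResponseMapping(exp3_alphas)
        multi = hb.generate_trials(exp3_design, fit_prior, params, rm, seed=3,
                                   n_participants=3)
        assert multi.participant_id.nunique() == 3
        # per-participant spread differs when kappas are drawn log-normally
        sds = multi.groupby("participant_id").reported_heading_deg.std()
        assert sds.nunique() == 3


class TestKinematics:
    def test_constant_profile_distance(self):
        assert hb.travel_distance(CONSTANT_SPEED) == pytest.approx(0.75, abs=1e-12)

    def test_triangular_profile_distance(self):
        assert hb.travel_distance(hb.TRIANGULAR_SPEED) == pytest.approx(0.75, abs=1e-12)

    def test_profiles_travel_identical_distances(self):
        assert hb.travel_distance(CONSTANT_SPEED) == pytest.approx(
            hb.travel_distance(hb.TRIANGULAR_SPEED), abs=1e-12
        )

    def test_zero_duration_constant(self):
        profile = SpeedProfile("constant", duration=0.0)
        assert hb.travel_distance(profile) == 0.0

    def test_inconsistent_triangle_duration_reports_both_times(self):
        bad = SpeedProfile("triangular", peak_speed=3.0, accel_magnitude=12.0,
                           duration=0.7)
        with pytest.raises(ValueError, match="0.7.*0.5"):
            hb.travel_distance(bad)

    @settings(max_examples=30, deadline=None)
    @given(speed=st.floats(0.1, 10.0), duration=st.floats(0.0, 5.0))
    def test_constant_distance_is_speed_times_time(self, speed, duration):
        profile = SpeedProfile("constant", constant_speed=speed, duration=duration)
        assert hb.travel_distance(profile) == pytest.approx(speed * duration, rel=1e-12)
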