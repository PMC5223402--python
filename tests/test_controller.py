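"""Feedback score, difficulty table, video-score machine, titration, sham."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from iinfb.controller import (
    DIFFICULTY_TABLE,
    EngineConfig,
    FeedbackState,
    ScheduleMismatchError,
    SessionLog,
    compute_nfb_score,
    difficulty_params,
    emg_gate_from_means,
    end_of_trial_update,
    run_session,
    step_video_score,
)
from iinfb.mu import BaselineProfile, ChannelPowerSet
from iinfb.synth import SubjectProfile, VirtualSubject, simulate_closed_loop_session


def make_baseline(power=50.0, emg_mean=1.6, emg_sd=0.1):
    return BaselineProfile(
        mu_power=ChannelPowerSet(power, power, power, power),
        emg_mean={"EMG_flex": emg_mean, "EMG_ext": emg_mean},
        emg_sd={"EMG_flex": emg_sd, "EMG_ext": emg_sd},
    )


def powers_from_ratios(c3, cp3, c4, cp4, base=50.0):
    return ChannelPowerSet(c3 * base, cp3 * base, c4 * base, cp4 * base)


class TestDifficultyTable:
    def test_level_1_row(self):
        row = difficulty_params(1)
        assert (row.lw, row.rw, row.lower, row.upper) == (1, 0.0, -4, 0)

    def test_level_9_row(self):
        row = difficulty_params(9)
        assert (row.rw, row.lower, row.upper) == (0.5, 2, 6)

    def test_level_15_row_degenerate_band(self):
        row = difficulty_params(15)
        assert (row.lower, row.upper) == (2, 2)

    def test_left_weight_always_one(self):
        assert all(r.lw == 1 for r in DIFFICULTY_TABLE.values())

    def test_right_weight_follows_ten_percent_rule(self):
        for level, row in DIFFICULTY_TABLE.items():
            if level <= 4:
                assert row.rw == 0
            elif level >= 14:
                assert row.rw == 1
            else:
                assert row.rw == pytest.approx((level - 4) / 10)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            difficulty_params(16)
        with pytest.raises(ValueError):
            difficulty_params(-2)


class TestNfbScore:
    def test_rest_state_score_is_minus_one_at_low_levels(self):
        # all ratios 1: each hemisphere term is log2(1+1)=1, score rw-lw
        score = compute_nfb_score(
            powers_from_ratios(1, 1, 1, 1), make_baseline(), difficulty_params(1)
        )
        assert score == pytest.approx(-1.0)

    def test_rest_state_score_is_zero_with_equal_weights(self):
        score = compute_nfb_score(
            powers_from_ratios(1, 1, 1, 1), make_baseline(), difficulty_params(14)
        )
        assert score == pytest.approx(0.0)

    def test_strong_lateralization_scores_two(self):
        score = compute_nfb_score(
            powers_from_ratios(0.25, 0.25, 1, 1),
            make_baseline(),
            difficulty_params(14),
        )
        assert score == pytest.approx(2.0)

    def test_normalized_variant_removes_rest_offset(self):
        score = compute_nfb_score(
            powers_from_ratios(1, 1, 1, 1), make_baseline(), difficulty_params(1),
            normalize=True,
        )
        assert score == pytest.approx(0.0)

    @given(
        st.floats(0.05, 4.0), st.floats(0.05, 4.0),
        st.integers(min_value=-1, max_value=15),
    )
    def test_decreasing_left_power_never_decreases_score(self, r_left, shrink, level):
        row = difficulty_params(level)
        base = make_baseline()
        hi = compute_nfb_score(powers_from_ratios(r_left, r_left, 1, 1), base, row)
        lo = compute_nfb_score(
            powers_from_ratios(r_left * min(shrink, 1.0), r_left, 1, 1), base, row
        )
        assert lo >= hi - 1e-12

    @given(st.floats(0.05, 4.0), st.integers(min_value=5, max_value=15))
    def test_increasing_right_power_never_decreases_score_when_weighted(
        self, r_right, level
    ):
        row = difficulty_params(level)
        base = make_baseline()
        lo = compute_nfb_score(powers_from_ratios(1, 1, r_right, r_right), base, row)
        hi = compute_nfb_score(
            powers_from_ratios(1, 1, r_right * 2, r_right), base, row
        )
        assert hi >= lo - 1e-12


class TestEmgGate:
    def test_well_above_threshold_flagged(self):
        base = make_baseline(emg_mean=1.0, emg_sd=0.2)
        means = {"EMG_flex": 1.0 + 2.5 * 0.2, "EMG_ext": 1.0}
        assert emg_gate_from_means(means, base) is True

    def test_at_baseline_mean_not_flagged(self):
        base = make_baseline(emg_mean=1.0, emg_sd=0.2)
        means = {"EMG_flex": 1.0, "EMG_ext": 1.0}
        assert emg_gate_from_means(means, base) is False

    def test_exactly_two_sd_not_flagged_strict_boundary(self):
        base = make_baseline(emg_mean=1.0, emg_sd=0.2)
        means = {"EMG_flex": 1.0 + 2.0 * 0.2, "EMG_ext": 1.0}
        assert emg_gate_from_means(means, base) is False

    def test_missing_channel_rejected(self):
        base = BaselineProfile(
            mu_power=ChannelPowerSet(1, 1, 1, 1),
            emg_mean={"EMG_flex": 1.0}, emg_sd={"EMG_flex": 0.1},
        )
        with pytest.raises(KeyError):
            emg_gate_from_means({"EMG_flex": 1.0, "EMG_ext": 1.0}, base)


class TestVideoScoreMachine:
    def test_win_increments_and_starts_lockout(self):
        row = difficulty_params(1)
        state = FeedbackState(video_score=3, lockout_remaining=0, level=1)
        out = step_video_score(state, row.upper + 1, row, emg_flag=False)
        assert (out.video_score, out.lockout_remaining) == (4, 4)

    def test_floor_at_one(self):
        row = difficulty_params(1)
        state = FeedbackState(video_score=1, lockout_remaining=0, level=1)
        out = step_video_score(state, row.lower - 1, row, emg_flag=False)
        assert out.video_score == 1

    def test_cap_at_six(self):
        row = difficulty_params(1)
        state = FeedbackState(video_score=6, lockout_remaining=0, level=1)
        out = step_video_score(state, row.upper + 10, row, emg_flag=False)
        assert out.video_score == 6

    def test_lockout_freezes_score_and_counts_down(self):
        row = difficulty_params(1)
        state = FeedbackState(video_score=4, lockout_remaining=2, level=1)
        out = step_video_score(state, row.upper + 10, row, emg_flag=False)
        assert (out.video_score, out.lockout_remaining) == (4, 1)

    def test_emg_resets_to_one_and_restarts_lockout(self):
        row = difficulty_params(1)
        state = FeedbackState(video_score=5, lockout_remaining=1, level=1)
        out = step_video_score(state, 100.0, row, emg_flag=True)
        assert (out.video_score, out.lockout_remaining) == (1, 4)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=200))
    def test_trajectory_invariants(self, scores):
        row = difficulty_params(2)
        state = FeedbackState()
        changes = []
        for i, s in enumerate(scores):
            new = step_video_score(state, s, row, emg_flag=False)
            assert 1 <= new.video_score <= 6
            assert abs(new.video_score - state.video_score) <= 1
            if new.video_score != state.video_score:
                changes.append(i)
            state = new
        for a, b in zip(changes, changes[1:]):
            assert b - a >= 5  # 4 full locked ticks between changes


class TestTitration:
    def test_mean_above_four_promotes(self):
        state = FeedbackState(level=3)
        assert end_of_trial_update([4.5] * 100, state) == 4

    def test_mean_below_two_demotes(self):
        state = FeedbackState(level=3)
        assert end_of_trial_update([1.5] * 100, state) == 2

    def test_midband_mean_holds_level(self):
        state = FeedbackState(level=3)
        assert end_of_trial_update([3.0] * 100, state) == 3

    def test_boundary_values_hold_level(self):
        state = FeedbackState(level=3)
        assert end_of_trial_update([4.0] * 100, state) == 3
        assert end_of_trial_update([2.0] * 100, state) == 3

    def test_level_one_needs_three_trial_streak_to_drop(self):
        assert end_of_trial_update(
            [1.5] * 100, FeedbackState(level=1, level1_streak=1)
        ) == 1
        assert end_of_trial_update(
            [1.5] * 100, FeedbackState(level=1, level1_streak=3)
        ) == 0

    def test_floor_at_minus_one_cap_at_fifteen(self):
        assert end_of_trial_update([1.0] * 100, FeedbackState(level=-1)) == -1
        assert end_of_trial_update([6.0] * 100, FeedbackState(level=15)) == 15

    def test_titration_uses_only_last_20s(self):
        # first 60 ticks all 6, last 40 all 1: mean of window is 1 -> demote
        state = FeedbackState(level=5)
        assert end_of_trial_update([6.0] * 60 + [1.0] * 40, state) == 4

    def test_trial_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            end_of_trial_update([3.0] * 10, FeedbackState(level=3))


class TestSessionOrchestration:
    def test_video_score_resets_each_trial_and_level_starts_at_one(
        self, default_session
    ):
        _, log = default_session
        first_ticks = log.ticks.groupby(["block", "trial"]).first()
        assert (first_ticks["video_score"] == 1).all()
        assert log.ticks.iloc[0]["level"] == 1

    def test_levels_change_only_at_trial_boundaries(self, default_session):
        _, log = default_session
        per_trial_levels = log.ticks.groupby(["block", "trial"])["level"].nunique()
        assert (per_trial_levels == 1).all()
        deltas = log.trials["level_after"] - log.trials["level_before"]
        assert deltas.abs().max() <= 1
        assert log.trials["level_after"].between(-1, 15).all()

    def test_sham_replay_is_bit_identical(self, default_session, engine_config):
        _, yoke = default_session
        sham = VirtualSubject(SubjectProfile(seed=1234))
        _, sham_log, _ = run_session(
            sham, engine_config, mode="sham", yoke=yoke,
            schedule_rng=np.random.default_rng(4),
        )
        assert sham_log.equals_presented(yoke)

    def test_sham_emg_logged_but_never_alters_stimulus(
        self, default_session, engine_config
    ):
        _, yoke = default_session
        # moderate rate: the 15-s baseline stays clean enough for the 2-SD
        # gate to remain sensitive, while the session has many bursts
        bursty = VirtualSubject(SubjectProfile(emg_burst_rate=6.0, seed=55))
        _, sham_log, _ = run_session(
            bursty, engine_config, mode="sham", yoke=yoke,
            schedule_rng=np.random.default_rng(4),
        )
        assert sham_log.ticks["emg_flag"].sum() > 0
        assert sham_log.equals_presented(yoke)

    def test_sham_requires_yoke(self, engine_config):
        with pytest.raises(ValueError):
            run_session(VirtualSubject(SubjectProfile()), engine_config, mode="sham")

    def test_yoke_schedule_mismatch_rejected(self, default_session):
        _, yoke = default_session
        truncated = SessionLog(
            ticks=yoke.ticks.iloc[:-1], trials=yoke.trials, mode="real"
        )
        with pytest.raises(ScheduleMismatchError):
            run_session(
                VirtualSubject(SubjectProfile(seed=2)), EngineConfig(),
                mode="sham", yoke=truncated,
            )

    def test_strong_quiet_subject_saturates_video_score_in_first_trial(self):
        prof = SubjectProfile(
            contra_ratio_task=0.1, responsiveness=0.0, noise_amp=0.0,
            blink_rate=0.0, emg_burst_rate=0.0, seed=3,
        )
        cfg = EngineConfig(blocks=1, trials_per_block=1, mi_trials=0)
        _, log = simulate_closed_loop_session(prof, cfg)
        assert log.ticks["video_score"].max() == 6
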