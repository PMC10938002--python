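"""Artifact flagging, trial exclusion, down-sampling, z-scoring, baselining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from pupilnum import stimuli as stim
from pupilnum.preprocess import (
    CleaningParams,
    DegenerateInputError,
    baseline_correct,
    downsample,
    exclude_saccade_trials,
    flag_invalid_samples,
    process_participant,
    zscore_participant,
)
from pupilnum.simulate import SimParams, session_events, simulate_participant, simulate_session

from conftest import CLEAN_KW


def _stream(t, pupil, gx=None, gy=None):
    n = len(t)
    return pd.DataFrame(
        {
            "t_s": t,
            "pupil_mm": pupil,
            "gaze_x_deg": np.zeros(n) if gx is None else gx,
            "gaze_y_deg": np.zeros(n) if gy is None else gy,
            "valid_flag": np.ones(n, dtype=np.int8),
        }
    )


class TestFlagInvalidSamples:
    def test_constant_trace_all_valid(self):
        t = np.arange(1000) / 500
        mask, intervals = flag_invalid_samples(_stream(t, np.full(1000, 5.0)))
        assert mask.all()
        assert intervals.shape == (0, 2)

    def test_fast_pair_both_flagged(self):
        # 0.1 mm over 2 ms = 50 mm/s > 25 mm/s
        mask, _ = flag_invalid_samples(_stream(np.array([0.0, 0.002]), [5.0, 4.9]))
        assert not mask.any()

    def test_slow_pair_kept(self):
        # 0.04 mm over 2 ms = 20 mm/s < 25 mm/s
        mask, _ = flag_invalid_samples(_stream(np.array([0.0, 0.002]), [5.0, 4.96]))
        assert mask.all()

    def test_sub_floor_dip_flagged_with_margins(self):
        t = np.arange(1000) / 500  # 2 s
        p = np.full(1000, 5.0)
        p[500:600] = 0.5  # 200 ms dip at t = 1.0..1.2
        mask, intervals = flag_invalid_samples(_stream(t, p))
        # dip plus 100 ms margins each side
        flagged = ~mask
        assert flagged[450:650].all()
        assert mask[:449].all() and mask[651:].all()
        assert len(intervals) == 1
        lo, hi = intervals[0]
        assert lo == pytest.approx(0.9, abs=0.01)
        assert hi == pytest.approx(1.3, abs=0.01)

    def test_empty_stream(self):
        mask, intervals = flag_invalid_samples(_stream(np.array([]), np.array([])))
        assert mask.size == 0 and intervals.shape == (0, 2)

    def test_overlapping_blink_margins_merge(self):
        t = np.arange(2000) / 500
        p = np.full(2000, 5.0)
        p[500:550] = 0.5
        p[570:620] = 0.5  # gap of 40 ms < 2 x 100 ms margin
        _, intervals = flag_invalid_samples(_stream(t, p))
        assert len(intervals) == 1


class TestArtifactRecall:
    """Injected blink/spike samples must be caught, clean data left alone."""

    def test_recall_on_injected_artifacts(self, default_params):
        params = default_params.replace(blink_rate_hz=0.2, spike_rate_hz=0.05)
        design = stim.build_design(["P1"], 18, seed=7)
        sess = simulate_session(design[design["session"] == 1], params, seed=8)
        mask, _ = flag_invalid_samples(sess.samples)
        t = sess.samples["t_s"].to_numpy()
        truth_bad = np.zeros(len(t), dtype=bool)
        for lo, hi in sess.truth["blink_intervals"]:
            truth_bad |= (t >= lo) & (t < hi)
        for i in sess.truth["spike_samples"]:
            truth_bad[i] = True
        recall = (~mask & truth_bad).sum() / truth_bad.sum()
        assert recall >= 0.95

    def test_false_flag_rate_on_clean_trace(self):
        params = SimParams(blink_rate_hz=0.0, spike_rate_hz=0.0, saccade_trial_prob=0.0)
        design = stim.build_design(["P1"], 18, seed=9)
        sess = simulate_session(design[design["session"] == 1], params, seed=10)
        mask, _ = flag_invalid_samples(sess.samples)
        assert (~mask).mean() <= 0.01


class TestExcludeSaccadeTrials:
    @staticmethod
    def _session_frame(gx, gy, n_trials=2):
        design = stim.build_design(["P1"], 1, seed=0)
        rows = design[design["session"] == 1].iloc[:n_trials].reset_index(drop=True)
        events = session_events(rows)
        n = int((60.0 + n_trials * 5.5) * 500)
        t = np.arange(n) / 500
        return _stream(t, np.full(n, 5.0), gx(t), gy(t)), events

    def test_steady_fixation_keeps_all(self):
        samples, events = self._session_frame(lambda t: 0 * t, lambda t: 0 * t)
        keep = exclude_saccade_trials(samples, events)
        assert keep["keep"].all()

    def test_single_sample_glitch_kept(self):
        def gx(t):
            x = np.zeros_like(t)
            x[int(61.0 * 500)] = 1.5  # one sample inside trial 1
            return x

        samples, events = self._session_frame(gx, lambda t: 0 * t)
        keep = exclude_saccade_trials(samples, events)
        assert keep["keep"].all()

    def test_sustained_excursion_drops_trial(self):
        def gx(t):
            x = np.zeros_like(t)
            x[(t >= 61.0) & (t < 61.2)] = 1.5  # 100 samples in trial 1
            return x

        samples, events = self._session_frame(gx, lambda t: 0 * t)
        keep = exclude_saccade_trials(samples, events).set_index("trial")
        assert not keep.loc[1, "keep"]
        assert keep.loc[2, "keep"]
        assert keep.loc[1, "reason"] == "saccade"

    def test_missing_gaze_raises(self):
        samples, events = self._session_frame(lambda t: 0 * t, lambda t: 0 * t)
        with pytest.raises(ValueError):
            exclude_saccade_trials(samples.drop(columns=["gaze_x_deg"]), events)

    def test_drop_fraction_matches_injected_rate(self, default_params):
        # pooled over 4 sessions x 90 trials; injected per-trial prob 0.055
        design = stim.build_design(["P1"], 18, seed=11)
        sessions = simulate_participant(design, default_params, seed=12)
        dropped = total = 0
        for sess in sessions:
            keep = exclude_saccade_trials(sess.samples, sess.events)
            dropped += (~keep["keep"]).sum()
            total += len(keep)
        p_hat = dropped / total
        se = np.sqrt(0.055 * 0.945 / total)
        assert abs(p_hat - 0.055) < 4 * se


class TestDownsample:
    def test_constant_bin_mean(self):
        t = np.arange(25) / 500
        out = downsample(_stream(t, np.full(25, 5.0)), np.ones(25, bool))
        assert len(out) == 1
        assert out["pupil"].iloc[0] == pytest.approx(5.0)

    def test_partial_validity_mean(self):
        t = np.arange(25) / 500
        p = np.full(25, 9.9)
        p[0], p[1] = 4.0, 6.0
        mask = np.zeros(25, bool)
        mask[:2] = True
        out = downsample(_stream(t, p), mask)
        assert out["pupil"].iloc[0] == pytest.approx(5.0)

    def test_empty_bin_missing(self):
        t = np.arange(50) / 500  # two bins
        mask = np.zeros(50, bool)
        mask[:25] = True
        out = downsample(_stream(t, np.full(50, 5.0)), mask)
        assert out["pupil"].iloc[0] == pytest.approx(5.0)
        assert np.isnan(out["pupil"].iloc[1])

    def test_grid_anchored_at_zero(self):
        t = np.arange(100) / 500
        out = downsample(_stream(t, np.full(100, 1.5)), np.ones(100, bool))
        assert np.allclose(out["t_s"], [0.0, 0.05, 0.1, 0.15])


class TestZscore:
    def test_three_point_example(self):
        z, med, sd = zscore_participant(np.array([4.0, 5.0, 6.0]))
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert med == 5.0 and sd == 1.0

    def test_output_median_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z, _, _ = zscore_participant(rng.normal(5, 0.4, size=1001))
        assert abs(np.median(z)) < 1e-12
        assert abs(np.std(z, ddof=1) - 1.0) < 1e-12

    def test_shift_invariance(self):
        x = np.array([4.1, 5.2, 5.9, 6.3])
        z1, _, _ = zscore_participant(x)
        z2, _, _ = zscore_participant(x + 1.0)
        assert np.allclose(z1, z2)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            zscore_participant(np.array([5.0]))
        with pytest.raises(DegenerateInputError):
            zscore_participant(np.full(10, 5.0))

    def test_nan_ignored_in_stats(self):
        x = np.array([4.0, np.nan, 5.0, 6.0])
        z, med, sd = zscore_participant(x)
        assert med == 5.0 and sd == 1.0
        assert np.isnan(z[1])


class TestBaselineCorrect:
    def test_constant_trace_zeroed(self):
        t = np.arange(-4, 20) / 20
        out = baseline_correct(t, np.full(24, 0.7))
        assert np.allclose(out, 0.0)

    def test_median_subtracted(self):
        t = np.array([-0.2, -0.1, 0.1, 0.5, 1.0])
        v = np.array([0.1, 0.3, 0.5, 2.0, 3.0])
        out = baseline_correct(t, v)
        assert np.allclose(out, v - 0.3)

    def test_window_median_exactly_zero(self):
        rng = np.random.default_rng(3)
        t = np.arange(-10, 40) / 20
        v = rng.normal(size=50)
        out = baseline_correct(t, v)
        win = out[(t >= -0.2) & (t < 0.2)]
        assert np.median(win) == pytest.approx(0.0, abs=1e-15)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        t = np.arange(-10, 40) / 20
        v = rng.normal(size=50)
        once = baseline_correct(t, v)
        twice = baseline_correct(t, once)
        assert np.allclose(once, twice)

    def test_empty_window_raises(self):
        t = np.array([0.5, 1.0])
        with pytest.raises(DegenerateInputError):
            baseline_correct(t, np.array([1.0, 2.0]))

    @settings(max_examples=50, deadline=None)
    @given(
        v=hnp.arrays(
            float,
            hst.integers(min_value=8, max_value=60),
            elements=hst.floats(-10, 10),
        )
    )
    def test_idempotence_property(self, v):
        t = (np.arange(len(v)) - 4) / 20
        once = baseline_correct(t, v)
        assert np.allclose(once, baseline_correct(t, once), equal_nan=True)


class TestMissingDataPropagation:
    """Flagged samples must never touch a bin mean, z statistic or baseline."""

    def test_poisoned_invalid_samples_change_nothing(self, default_params):
        design = stim.build_design(["P1"], 3, seed=13)
        sess = simulate_session(design[design["session"] == 1], default_params, seed=14)
        mask, _ = flag_invalid_samples(sess.samples)
        binned = downsample(sess.samples, mask)

        poisoned = sess.samples.copy()
        poisoned.loc[~mask, "pupil_mm"] = 1e9
        binned_p = downsample(poisoned, mask)
        pd.testing.assert_frame_equal(binned, binned_p)

        z, med, sd = zscore_participant(binned["pupil"].to_numpy())
        z_p, med_p, sd_p = zscore_participant(binned_p["pupil"].to_numpy())
        assert med == med_p and sd == sd_p
        t_rel = binned["t_s"].to_numpy() - 62.5  # first test onset
        np.testing.assert_array_equal(
            baseline_correct(t_rel, z), baseline_correct(t_rel, z_p)
        )


class TestProcessParticipant:
    def test_grid_spacing_and_baseline(self, participant_sessions):
        proc = process_participant(participant_sessions)
        trials = proc.trials
        assert not trials.empty
        for _, grp in trials.groupby(
            ["session", "trial", "align"], sort=False
        ):
            assert np.allclose(np.diff(np.sort(grp["t_rel"].unique())), 0.05)
        test_locked = trials[trials["align"] == "test"]
        for _, grp in test_locked.groupby(["session", "trial"]):
            win = grp[(grp["t_rel"] >= -0.2) & (grp["t_rel"] < 0.2 - 1e-9)]["z"]
            win = win.dropna()
            assert np.median(win) == pytest.approx(0.0, abs=1e-12)

    def test_attrition_accounting(self, participant_sessions):
        proc = process_participant(participant_sessions)
        n_trials_in = sum(len(s.design) for s in participant_sessions)
        assert len(proc.exclusions) == n_trials_in
        kept_ids = proc.trials.groupby(["session", "trial"]).ngroups
        assert kept_ids == int(proc.exclusions["kept"].sum())

    def test_clean_sessions_drop_nothing(self, clean_params):
        design = stim.build_design(["P1"], 2, seed=15)
        sessions = simulate_participant(design, clean_params, seed=16)
        proc = process_participant(sessions)
        assert proc.exclusions["kept"].all()
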