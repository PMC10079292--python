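"""Tests for trial parsing, bouts, movement epochs, and approach detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fiberphot import behavior as bh


def build_log(trials, schedule_limit=5.0):
    """Event log from a list of per-trial press-offset lists.

    Completed trials (>= 5 presses) get pellet delivery, head entry and
    retraction at retrieval; others retract at the time limit.
    """
    rows = []
    t = 0.0
    for k, presses in enumerate(trials):
        t += 3.0
        t_ext = t
        rows.append((t_ext, "lever_extension", k))
        for dp in presses:
            rows.append((t_ext + dp, "press", k))
        if len(presses) >= 5:
            t_del = t_ext + presses[-1] + 0.05
            rows.append((t_del, "pellet_delivery", k))
            rows.append((t_del + 0.8, "head_entry", k))
            t_ret = t_del + 0.8
        else:
            t_ret = t_ext + schedule_limit
        rows.append((t_ret, "lever_retraction", k))
        t = t_ret + 8.0
    df = pd.DataFrame(sorted(rows), columns=["t_s", "label", "trial_index"])
    return bh.EventLog(df)


class TestParseTrials:
    def test_five_presses_within_limit_completed(self):
        log = build_log([[1, 2, 3, 4, 4.9]])
        (tr,) = bh.parse_trials(log, "FR5-5s")
        assert tr.outcome == "completed"
        assert tr.initiation_latency_s == pytest.approx(1.0)
        assert tr.retrieval_latency_s == pytest.approx(0.8)

    def test_one_to_four_presses_incomplete(self):
        log = build_log([[1, 2, 3]])
        (tr,) = bh.parse_trials(log, "FR5-5s")
        assert tr.outcome == "incomplete"
        assert np.isnan(tr.retrieval_latency_s)

    def test_no_press_omission(self):
        log = build_log([[]])
        (tr,) = bh.parse_trials(log, "FR5-5s")
        assert tr.outcome == "omission"
        assert np.isnan(tr.initiation_latency_s)

    def test_press_outside_trial_raises(self):
        log = build_log([[1, 2]])
        df = pd.concat([log.records,
                        pd.DataFrame([{"t_s": 0.5, "label": "press",
                                       "trial_index": pd.NA, "light_flag": False}])])
        df = df.sort_values("t_s").reset_index(drop=True)
        with pytest.raises(ValueError, match="outside"):
            bh.parse_trials(bh.EventLog(df), "FR5-5s")

    def test_outcome_partition_on_mixed_session(self):
        log = build_log([[1, 2, 3, 4, 4.5], [1], [], [0.5, 1, 1.5, 2, 2.5], [2, 3]])
        trials = bh.parse_trials(log, "FR5-5s")
        counts = {oc: sum(t.outcome == oc for t in trials) for oc in bh.OUTCOMES}
        assert counts == {"completed": 2, "incomplete": 2, "omission": 1}
        assert sum(counts.values()) == len(trials)


class TestSessionPerformance:
    def test_all_completed(self):
        log = build_log([[1, 2, 3, 4, 4.5]] * 10)
        perf = bh.session_performance(bh.parse_trials(log, "FR5-5s"))
        assert perf.loc["all", "pct_completed"] == 100.0
        assert perf.loc["all", "pct_omission"] == 0.0

    def test_rates_60_20_20(self):
        log = build_log([[1, 2, 3, 4, 4.5]] * 6 + [[1]] * 2 + [[]] * 2)
        perf = bh.session_performance(bh.parse_trials(log, "FR5-5s"))
        assert perf.loc["all", "pct_completed"] == pytest.approx(60.0)
        assert perf.loc["all", "pct_incomplete"] == pytest.approx(20.0)
        assert perf.loc["all", "pct_omission"] == pytest.approx(20.0)

    def test_each_stratum_sums_to_100(self):
        from fiberphot.synth import BehaviorSimConfig, simulate_fr_session
        log = simulate_fr_session(BehaviorSimConfig(
            schedule="FR5-5s", n_trials=60, light_fraction=0.33,
            p_engage=0.7, seed=3))
        perf = bh.session_performance(bh.parse_trials(log, "FR5-5s"))
        sums = perf[[f"pct_{oc}" for oc in bh.OUTCOMES]].sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no trials"):
            bh.session_performance([])


def brute_force_bouts(licks):
    """Independent bout oracle: scan runs directly."""
    bouts = []
    run = []
    for t in licks:
        if not run or t - run[-1] < 2.0:
            run.append(t)
        else:
            if len(run) >= 2:
                bouts.append(run)
            run = [t]
    if len(run) >= 2:
        bouts.append(run)
    return bouts


class TestDetectBouts:
    def test_worked_example(self):
        bouts = bh.detect_bouts([0, 0.5, 3.0, 3.4, 3.9, 10.5])
        assert [(b.start_s, b.end_s) for b in bouts] == [(0.0, 0.5), (3.0, 3.9)]

    def test_exact_two_second_interval_splits(self):
        bouts = bh.detect_bouts([0.0, 1.0, 3.0, 4.0])  # gap of exactly 2.0 s
        assert len(bouts) == 2

    def test_empty(self):
        assert bh.detect_bouts([]) == []

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            bh.detect_bouts([3.0, 1.0])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        licks = np.cumsum(rng.exponential(1.2, size=rng.integers(0, 40)))
        got = bh.detect_bouts(licks)
        expected = brute_force_bouts(list(licks))
        assert len(got) == len(expected)
        for b, exp in zip(got, expected):
            assert b.lick_times_s == pytest.approx(exp)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_bout_compression_reconstructs_input(self, seed):
        """Bout licks plus discarded singletons reproduce the input train."""
        rng = np.random.default_rng(seed)
        licks = np.sort(rng.uniform(0, 60, size=rng.integers(0, 30)))
        bouts = bh.detect_bouts(licks)
        in_bouts = [t for b in bouts for t in b.lick_times_s]
        singles = [t for t in licks if not any(
            b.start_s <= t <= b.end_s for b in bouts)]
        assert sorted(in_bouts + singles) == pytest.approx(list(licks))


def square_wave_trajectory(speeds, dt=0.05):
    """Straight-line path with a prescribed piecewise-constant speed profile."""
    v = np.concatenate([np.full(int(round(d / dt)), s) for s, d in speeds])
    x = np.concatenate(([0.0], np.cumsum(v * dt)))[:-1]
    t = np.arange(v.size) * dt
    return pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": np.zeros_like(x)})


class TestMovementEpochs:
    def test_stationary_trajectory_yields_nothing(self):
        traj = pd.DataFrame({"t_s": np.arange(100) * 0.05,
                             "x_cm": np.full(100, 5.0),
                             "y_cm": np.full(100, 5.0)})
        assert bh.detect_movement_epochs(traj) == []

    def test_square_wave_profile_recovered(self):
        traj = square_wave_trajectory([(0.0, 2.0), (10.0, 2.0), (0.0, 2.0),
                                       (10.0, 1.5), (0.0, 2.0)])
        epochs = bh.detect_movement_epochs(traj)
        assert len(epochs) == 2
        assert epochs[0].onset_s == pytest.approx(2.0, abs=0.3)
        assert epochs[0].offset_s == pytest.approx(4.0, abs=0.3)

    def test_short_epochs_dropped(self):
        traj = square_wave_trajectory([(0.0, 2.0), (10.0, 0.2), (0.0, 2.0)])
        assert bh.detect_movement_epochs(traj, min_dur_s=0.5) == []

    def test_peak_not_before_onset(self):
        traj = square_wave_trajectory([(0.0, 1.0), (5.0, 1.0), (12.0, 1.0),
                                       (3.0, 1.0), (0.0, 1.0)])
        for ep in bh.detect_movement_epochs(traj):
            assert ep.onset_s <= ep.t_peak_s <= ep.offset_s

    def test_nonuniform_sampling_raises(self):
        traj = pd.DataFrame({"t_s": [0, 0.05, 0.2, 0.25],
                             "x_cm": [0, 1, 2, 3], "y_cm": [0, 0, 0, 0]})
        with pytest.raises(ValueError, match="uniform"):
            bh.detect_movement_epochs(traj)


class TestApproaches:
    def straight_path(self):
        t = np.arange(200) * 0.05
        return pd.DataFrame({"t_s": t, "x_cm": t * 5.0, "y_cm": np.zeros_like(t)})

    def test_path_through_target_one_event(self):
        events = bh.detect_approaches(self.straight_path(), [(25.0, 0.0)])
        assert len(events) == 1
        # entry when the 5 cm radius is first crossed
        assert events[0].t_entry_s == pytest.approx(4.0, abs=0.1)

    def test_far_target_no_event(self):
        assert bh.detect_approaches(self.straight_path(), [(25.0, 40.0)]) == []

    def test_dwell_inside_single_event(self):
        t = np.arange(300) * 0.05
        x = np.minimum(t * 5.0, 25.0)  # run to the target and stop on it
        traj = pd.DataFrame({"t_s": t, "x_cm": x, "y_cm": np.zeros_like(t)})
        assert len(bh.detect_approaches(traj, [(25.0, 0.0)])) == 1

    def test_reentry_counts_twice(self):
        x = np.concatenate([np.linspace(0, 25, 50), np.linspace(25, 0, 50),
                            np.linspace(0, 25, 50)])
        traj = pd.DataFrame({"t_s": np.arange(x.size) * 0.05, "x_cm": x,
                             "y_cm": np.zeros_like(x)})
        assert len(bh.detect_approaches(traj, [(25.0, 0.0)])) == 2


class TestPrematureHeadEntries:
    def test_entries_before_final_press_included(self):
        log = build_log([[1, 2, 3, 4, 4.5]])
        df = pd.concat([log.records, pd.DataFrame([
            {"t_s": 3.5, "label": "head_entry", "trial_index": 0, "light_flag": False},
        ])]).sort_values("t_s").reset_index(drop=True)
        log2 = bh.EventLog(df)
        trials = bh.parse_trials(log2, "FR5-5s")
        assert bh.premature_head_entries(trials, log2) == [3.5]

    def test_retrieval_entry_excluded(self):
        log = build_log([[1, 2, 3, 4, 4.5]])
        trials = bh.parse_trials(log, "FR5-5s")
        # the only head entry is the post-delivery retrieval entry
        assert bh.premature_head_entries(trials, log) == []

    def test_no_entries(self):
        log = build_log([[1]])
        trials = bh.parse_trials(log, "FR5-5s")
        assert bh.premature_head_entries(trials, log) == []


class TestAdvancementCriterion:
    @pytest.mark.parametrize("counts,expected", [
        ([35, 40], True),          # two consecutive sessions at criterion
        ([35, 20, 40], False),     # interrupted run
        ([10, 31, 30, 5], True),   # run in the middle
        ([29, 29, 29], False),
        ([], False),
    ])
    def test_consecutive_sessions_rule(self, counts, expected):
        assert bh.meets_advancement_criterion(counts) is expected
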