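import numpy as np
import pandas as pd
import pytest

import limbwear as lw
from limbwear.io_formats import read_behaviour_epochs, write_behaviour_epochs
from limbwear.synthetic_data import (
    SteppingTruth,
    TruthSchedule,
    interval_jaccard,
    match_events,
)


def _truth_with_wear(intervals, n_days=1):
    """Hand-built schedule: wear intervals only, no excursions or stepping."""
    start = pd.Timestamp("2025-03-03")
    return TruthSchedule(
        participant_id="P1",
        group="previous_user",
        seed=0,
        start=start,
        end=start + pd.Timedelta(days=n_days),
        days=[],
        sleep_intervals=[],
        wear_intervals=[(pd.Timestamp(a), pd.Timestamp(b)) for a, b in intervals],
        stepping_bouts=[],
    )


class TestSimulateTruth:
    def test_seeded_determinism(self):
        cfg = lw.CohortConfig(n_participants=3, n_days=2, seed=9)
        t1, t2 = lw.simulate_truth(cfg), lw.simulate_truth(cfg)
        for a, b in zip(t1, t2):
            assert a.wear_intervals == b.wear_intervals
            assert a.stepping_bouts == b.stepping_bouts
            assert [d.excursions for d in a.days] == [d.excursions for d in b.days]

    def test_don_at_departure_structure(self):
        cfg = lw.CohortConfig(n_participants=4, n_days=3, seed=3, don_at_departure_prob=1.0)
        for truth in lw.simulate_truth(cfg):
            dons = truth.don_times()
            doffs = truth.doff_times()
            for day in truth.days:
                for dep, ret in day.excursions:
                    assert any(
                        pd.Timedelta(0) < dep - d <= pd.Timedelta(minutes=10) for d in dons
                    ), f"departure {dep} lacks a preceding don"
                    assert any(
                        pd.Timedelta(0) < d - ret <= pd.Timedelta(minutes=30) for d in doffs
                    ), f"return {ret} lacks a following doff"

    def test_wear_target_realised_on_average(self):
        cfg = lw.CohortConfig(
            n_participants=20,
            n_days=7,
            seed=1,
            wear_hours_mean={"previous_user": 10.0, "new_user": 10.0},
        )
        truths = lw.simulate_truth(cfg)
        means = [t.daily_wear_hours().mean() for t in truths]
        assert abs(np.mean(means) - 10.0) < 1.0

    def test_wear_gaps_respect_detector_run(self):
        cfg = lw.CohortConfig(n_participants=4, n_days=4, seed=12)
        for truth in lw.simulate_truth(cfg):
            for (_, b), (a, _) in zip(truth.wear_intervals, truth.wear_intervals[1:]):
                assert a - b >= pd.Timedelta(minutes=60)

    def test_infeasible_config_rejected(self):
        with pytest.raises(lw.GenerationError):
            lw.CohortConfig(excursions_per_day=10, excursion_duration_min_mean=200)
        with pytest.raises(lw.GenerationError):
            lw.CohortConfig(don_at_departure_prob=1.5)


class TestRenderWrist:
    def test_fully_doffed_day_gives_zero_vm(self):
        cfg = lw.CohortConfig(n_participants=1, n_days=1, seed=4)
        truth = _truth_with_wear([])
        series = lw.vector_magnitude(lw.emulate_counts(lw.render_wrist(truth, cfg)))
        assert (series.vm == 0).all()

    def test_single_wear_block_recovered(self):
        cfg = lw.CohortConfig(n_participants=1, n_days=1, seed=4)
        truth = _truth_with_wear([("2025-03-03 08:00", "2025-03-03 18:00")])
        wrist = lw.render_wrist(truth, cfg)
        mask = lw.detect_wear(lw.vector_magnitude(lw.emulate_counts(wrist)))
        daily = lw.daily_wear_summary(mask)
        assert daily["worn_hours"].iloc[0] == pytest.approx(10.0, abs=0.25)
        events = lw.extract_events(mask)
        assert match_events([truth.wear_intervals[0][0]], [e.time for e in events if e.kind == "don"]) == 1.0
        assert match_events([truth.wear_intervals[0][1]], [e.time for e in events if e.kind == "doff"]) == 1.0

    def test_doubling_burst_amplitude_never_reduces_counts(self):
        truth = _truth_with_wear([("2025-03-03 08:00", "2025-03-03 12:00")])
        base = lw.CohortConfig(n_participants=1, n_days=1, seed=4, burst_amplitude_g=0.5)
        loud = lw.CohortConfig(n_participants=1, n_days=1, seed=4, burst_amplitude_g=1.0)
        c0 = lw.emulate_counts(lw.render_wrist(truth, base)).counts
        c1 = lw.emulate_counts(lw.render_wrist(truth, loud)).counts
        assert (c1[:, 0] >= c0[:, 0]).all()

    def test_render_is_seed_deterministic(self):
        cfg = lw.CohortConfig(n_participants=1, n_days=1, seed=5)
        truth = _truth_with_wear([("2025-03-03 09:00", "2025-03-03 11:00")])
        w1, w2 = lw.render_wrist(truth, cfg), lw.render_wrist(truth, cfg)
        np.testing.assert_array_equal(w1.samples, w2.samples)


@pytest.fixture(scope="module")
def one_truth():
    cfg = lw.CohortConfig(n_participants=1, n_days=2, seed=6)
    return lw.simulate_truth(cfg)[0], cfg


class TestRenderThigh:

    def test_sleep_epochs_are_primary_lying(self, one_truth):
        truth, cfg = one_truth
        table = lw.render_thigh(truth, cfg)
        a, b = truth.sleep_intervals[0]
        inner = table.data[(table.epoch_start >= a.ceil("min")) & (table.epoch_start < b.floor("min"))]
        assert (inner["primary_lying"] == 60).all()

    def test_steps_conserve_cadence_times_duration(self, one_truth):
        truth, cfg = one_truth
        table = lw.render_thigh(truth, cfg)
        assert int(table.data["steps"].sum()) == truth.total_steps()

    def test_transition_walk_fires_exactly_one_event(self):
        cfg = lw.CohortConfig(n_participants=1, n_days=1, seed=6)
        start = pd.Timestamp("2025-03-03")
        truth = TruthSchedule(
            participant_id="P1", group="previous_user", seed=0,
            start=start, end=start + pd.Timedelta(days=1), days=[],
            sleep_intervals=[], wear_intervals=[],
            stepping_bouts=[SteppingTruth(start=pd.Timestamp("2025-03-03 10:00:40"), duration_s=90, cadence_spm=100.0)],
        )
        table = lw.render_thigh(truth, cfg)
        events = lw.detect_transitions(lw.extract_stepping_bouts(table))
        assert len(events) == 1
        assert abs((events[0].time - pd.Timestamp("2025-03-03 10:00:40")).total_seconds()) <= 60

    def test_round_trip_through_io(self, one_truth, tmp_path):
        truth, cfg = one_truth
        table = lw.render_thigh(truth, cfg)
        write_behaviour_epochs(table, tmp_path / "t.csv")
        back = read_behaviour_epochs(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(back.data, table.data, check_freq=False)

    def test_missing_intervals_drop_rows(self):
        cfg = lw.CohortConfig(n_participants=1, n_days=2, seed=8, low_coverage_day_prob=1.0)
        truth = lw.simulate_truth(cfg)[0]
        table = lw.render_thigh(truth, cfg)
        expected_missing = int(cfg.low_coverage_missing_h * 60) * cfg.n_days
        assert 2 * 1440 - len(table) == expected_missing


class TestEndToEndRecovery:
    def test_small_cohort_recovery(self, small_results):
        for truth, res in small_results:
            tw = truth.daily_wear_hours()
            dw = res.daily_wear.set_index("date")["worn_hours"]
            assert (dw - tw).abs().max() <= 0.25

            dons = [e.time for e in res.events if e.kind == "don"]
            doffs = [e.time for e in res.events if e.kind == "doff"]
            assert match_events(truth.don_times(), dons) >= 0.95
            assert match_events(truth.doff_times(), doffs) >= 0.95

            ta = truth.daily_away_hours()
            for day in res.participation:
                if day.reason is None:
                    assert abs(day.away_hours - ta[day.date]) <= 0.5
                    true_iv = [e for d in truth.days if d.date == day.date for e in d.excursions]
                    if true_iv:
                        assert interval_jaccard(day.away_intervals, true_iv) >= 0.9

    def test_post_don_exceeds_post_doff(self, small_results):
        post_don, post_doff = [], []
        for _, res in small_results:
            for s in res.window_stats:
                if s.complete:
                    (post_don if s.event.kind == "don" else post_doff).append(s.post_stepping_min)
        assert np.mean(post_don) > np.mean(post_doff)
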