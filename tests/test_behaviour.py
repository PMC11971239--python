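import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import limbwear as lw
from limbwear.behaviour import attach_heading

from tutils import make_behaviour_table, oracle_bouts


class TestLabelDominant:
    def test_plain_majority(self):
        table = make_behaviour_table(n=1, stepping=[40])
        assert lw.label_dominant(table).iloc[0] == "stepping"

    def test_tie_broken_by_priority(self):
        # sedentary 30 / upright 30: upright outranks sedentary
        table = make_behaviour_table(n=1)
        df = table.data.copy()
        df.loc[df.index[0], ["sedentary", "upright"]] = [30, 30]
        assert lw.label_dominant(lw.BehaviourEpochTable(df)).iloc[0] == "upright"

    def test_full_non_wear_epoch(self):
        table = make_behaviour_table(n=1, non_wear=[60])
        assert lw.label_dominant(table).iloc[0] == "non_wear"


class TestSteppingBouts:
    @pytest.mark.parametrize(
        "stepping,expected",
        [
            ([60, 60, 60], [(0, 180.0)]),
            ([60, 0, 60], [(0, 60.0), (2, 60.0)]),
            ([58, 57], [(0, 115.0)]),
            ([60, 30], [(0, 90.0)]),  # partial trailing epoch joins the bout
            ([0, 45, 0], []),  # sub-threshold epoch alone is no bout
        ],
    )
    def test_reconstruction(self, stepping, expected):
        pad = [0] * 2
        table = make_behaviour_table(n=len(stepping) + 4, stepping=pad + stepping + pad)
        bouts = lw.extract_stepping_bouts(table)
        got = [((b.start - table.epoch_start[0]).total_seconds() / 60 - 2, b.duration) for b in bouts]
        assert got == [(float(i), d) for i, d in expected]

    def test_partial_epoch_between_cores_attaches_to_neither(self):
        table = make_behaviour_table(n=7, stepping=[0, 60, 40, 60, 0, 0, 0])
        bouts = lw.extract_stepping_bouts(table)
        assert [b.duration for b in bouts] == [60.0, 60.0]

    def test_grid_gap_breaks_run(self):
        table = make_behaviour_table(n=5, stepping=[60, 60, 60, 60, 60], drop=[2])
        bouts = lw.extract_stepping_bouts(table)
        assert [b.duration for b in bouts] == [120.0, 120.0]

    def test_event_stream_passthrough(self):
        ext = [lw.SteppingBout(start=pd.Timestamp("2025-01-06 10:00"), duration=90.0, source="event_stream")]
        table = make_behaviour_table(n=2)
        assert lw.extract_stepping_bouts(table, mode="event_stream", event_bouts=ext) == ext
        with pytest.raises(lw.ConfigError):
            lw.extract_stepping_bouts(table, mode="nope")

    @given(st.lists(st.sampled_from([0, 10, 30, 54, 55, 58, 60]), min_size=1, max_size=40))
    def test_matches_naive_oracle(self, stepping):
        table = make_behaviour_table(n=len(stepping), stepping=stepping)
        got = [
            (int((b.start - table.epoch_start[0]).total_seconds() // 60), b.duration)
            for b in lw.extract_stepping_bouts(table)
        ]
        want = [(i, float(d)) for i, d in oracle_bouts(stepping)]
        assert got == want


class TestTransitions:
    def test_long_bout_fires(self):
        b = lw.SteppingBout(start=pd.Timestamp("2025-01-06 10:00"), duration=70.0)
        events = lw.detect_transitions([b])
        assert len(events) == 1 and events[0].rule == "long_bout"
        assert events[0].time == b.start

    def test_exactly_sixty_seconds_does_not_fire(self):
        b = lw.SteppingBout(start=pd.Timestamp("2025-01-06 10:00"), duration=60.0)
        assert lw.detect_transitions([b]) == []

    def test_straight_line_rule(self):
        start = pd.Timestamp("2025-01-06 10:00")
        t = pd.date_range(start, periods=41, freq="1s")
        # 30 s nearly straight (4° drift), then a sharp turn
        heading = np.concatenate([np.linspace(0, 4, 30), np.linspace(4, 180, 11)])
        bout = lw.SteppingBout(start=start, duration=40.0)
        (annotated,) = attach_heading(
            [bout], pd.DataFrame({"time": t, "heading_deg": heading})
        )
        assert annotated.heading_span <= 30.0
        events = lw.detect_transitions([annotated])
        assert len(events) == 1 and events[0].rule == "straight_line"

    def test_short_winding_bout_silent(self):
        start = pd.Timestamp("2025-01-06 10:00")
        t = pd.date_range(start, periods=21, freq="1s")
        heading = np.cumsum(np.full(21, 15.0))  # constantly turning
        bout = lw.SteppingBout(start=start, duration=20.0)
        (annotated,) = attach_heading([bout], pd.DataFrame({"time": t, "heading_deg": heading}))
        assert lw.detect_transitions([annotated]) == []

    @given(st.integers(55, 200))
    def test_raising_long_threshold_is_monotone(self, long_s):
        bouts = [
            lw.SteppingBout(start=pd.Timestamp("2025-01-06 10:00") + pd.Timedelta(minutes=10 * i), duration=d)
            for i, d in enumerate([30.0, 61.0, 90.0, 150.0, 59.0])
        ]
        n_lo = len(lw.detect_transitions(bouts, long_s=long_s))
        n_hi = len(lw.detect_transitions(bouts, long_s=long_s + 20))
        assert n_hi <= n_lo


class TestSleep:
    def test_overnight_block(self):
        lying = [60] * 480  # 22:00 → 06:00
        table = make_behaviour_table(start="2025-01-06 22:00", n=480, lying=lying)
        periods = lw.detect_sleep(lw.label_dominant(table))
        assert len(periods) == 1
        assert periods[0].duration_h == pytest.approx(8.0)

    def test_brief_interruption_merged(self):
        lying = np.full(480, 60)
        lying[200:210] = 0  # 10-min sedentary interruption
        table = make_behaviour_table(start="2025-01-06 22:00", n=480, lying=lying)
        periods = lw.detect_sleep(lw.label_dominant(table), interruption_tolerance_min=15)
        assert len(periods) == 1
        assert periods[0].duration_h == pytest.approx(8.0)

    def test_no_lying_gives_empty(self):
        table = make_behaviour_table(n=480)
        assert lw.detect_sleep(lw.label_dominant(table)) == []

    def test_short_nap_dropped(self):
        table = make_behaviour_table(n=480, lying=[60] * 60 + [0] * 420)
        assert lw.detect_sleep(lw.label_dominant(table), min_sleep_hours=3) == []


def _day_table(n_days=1, missing_hours=0.0):
    n = 1440 * n_days
    lying = np.zeros(n, dtype=int)
    for d in range(n_days + 1):
        s, e = d * 1440 - 90, d * 1440 + 390  # 22:30 → 06:30
        lying[max(s, 0) : min(e, n)] = 60
    drop = ()
    if missing_hours:
        drop = range(600, 600 + int(missing_hours * 60))
    return make_behaviour_table(start="2025-01-06 00:00", n=n, lying=lying, drop=drop)


def _transition(hhmm):
    return lw.TransitionEvent(time=pd.Timestamp(f"2025-01-06 {hhmm}"), rule="long_bout")


def _sleeps():
    return [
        lw.SleepPeriod(pd.Timestamp("2025-01-05 22:30"), pd.Timestamp("2025-01-06 06:30")),
        lw.SleepPeriod(pd.Timestamp("2025-01-06 22:30"), pd.Timestamp("2025-01-07 06:30")),
    ]


class TestClassifyHomeAway:
    def test_single_excursion_toggle(self):
        days = lw.classify_home_away([_transition("09:00"), _transition("17:00")], _sleeps(), _day_table())
        assert days[0].away_hours == pytest.approx(8.0)
        assert days[0].valid

    def test_no_transitions_means_home_all_day(self):
        days = lw.classify_home_away([], _sleeps(), _day_table())
        assert days[0].away_hours == 0.0

    def test_odd_transition_count_closes_at_returning_anchor(self):
        evs = [_transition("09:00"), _transition("12:00"), _transition("17:00")]
        days = lw.classify_home_away(evs, _sleeps(), _day_table())
        # pairs (09→12); the 17:00 event is the returning anchor, adding nothing
        assert days[0].away_hours == pytest.approx(3.0)

    def test_anchors_mode_reports_span(self):
        evs = [_transition("09:00"), _transition("12:00"), _transition("17:00")]
        days = lw.classify_home_away(evs, _sleeps(), _day_table(), mode="anchors")
        assert days[0].away_hours == pytest.approx(8.0)

    def test_low_coverage_day_flagged_invalid(self):
        days = lw.classify_home_away([], _sleeps(), _day_table(missing_hours=4.5))
        assert days[0].observed_hours == pytest.approx(19.5)
        assert not days[0].valid

    def test_missing_sleep_anchor_reports_reason(self):
        days = lw.classify_home_away([_transition("09:00")], [], _day_table())
        assert days[0].reason == "no_sleep_anchor"
        assert np.isnan(days[0].away_hours)

    def test_away_bounded_by_waking_hours(self):
        evs = [_transition("07:00"), _transition("22:00")]
        days = lw.classify_home_away(evs, _sleeps(), _day_table())
        waking = 16.0  # 06:30 → 22:30
        assert days[0].away_hours <= waking
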