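"""Thigh-stream behaviour analysis: dominant labels, stepping bouts, sleep and
home/away classification.

The thigh monitor's vendor software reports, per 60-s epoch, the seconds spent
in each posture/activity class plus a step count.  This module derives from
that table:

* a dominant class per epoch;
* continuous stepping bouts (reconstructed from minute epochs);
* transition events — walks long enough (> 60 s) or straight enough (> 25 s in
  a straight line, when a heading series is available) that they very likely
  mark movement between environments rather than within the home;
* sleep periods (runs of the sleep-associated "primary lying" class), which
  anchor each day's home/away state machine;
* a per-day home/away breakdown: the first transition after the morning sleep
  marks leaving home, the last transition before the evening sleep marks
  returning; intermediate transitions toggle the state.  A day counts toward
  group summaries only when more than 20 h of monitor data were collected
  ("valid day").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import ACTIVITY_CLASSES, BehaviourEpochTable

#: Tie-break priority for the dominant class (first wins).  Rarer, more
#: specific classes outrank generic ones so that ties are deterministic.
DOMINANCE_PRIORITY = (
    "stepping",
    "cycling",
    "upright",
    "seated_transport",
    "sedentary",
    "secondary_lying",
    "primary_lying",
    "non_wear",
)

LONG_BOUT = "long_bout"
STRAIGHT_LINE = "straight_line"


@dataclass
class SteppingBout:
    """A maximal period of continuous stepping.

    ``duration`` is the summed stepping seconds; ``end = start + duration`` is
    the stepping-time extent (minute epochs cannot localise pauses within an
    epoch).  ``heading_span`` is the smallest cumulative |heading change| over
    any sub-segment of the straight-line rule's length, when heading data were
    attached.
    """

    start: pd.Timestamp
    duration: float
    source: str = "epoch_reconstruction"
    heading_span: float | None = None

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration)


@dataclass(frozen=True)
class TransitionEvent:
    """A stepping bout qualifying as movement between environments."""

    time: pd.Timestamp  # bout start
    rule: str  # "long_bout" | "straight_line"


@dataclass(frozen=True)
class SleepPeriod:
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class DailyParticipation:
    """Midnight-to-midnight home/away summary for one day."""

    date: pd.Timestamp
    away_hours: float
    observed_hours: float
    valid: bool
    away_intervals: list[tuple[pd.Timestamp, pd.Timestamp]] = field(default_factory=list)
    reason: str | None = None  # set when the day could not be classified


def label_dominant(table: BehaviourEpochTable) -> pd.Series:
    """Dominant activity class per epoch (maximal seconds, fixed tie-break)."""
    cols = list(DOMINANCE_PRIORITY)
    arr = table.data[cols].to_numpy(dtype=float)
    idx = arr.argmax(axis=1)  # argmax keeps the first (= highest priority) max
    labels = np.array(cols, dtype=object)[idx]
    return pd.Series(labels, index=table.epoch_start, name="dominant")


def extract_stepping_bouts(
    table: BehaviourEpochTable,
    mode: str = "epoch_reconstruction",
    min_epoch_stepping_s: float = 55.0,
    *,
    extend_partial_edges: bool = True,
    event_bouts: list[SteppingBout] | None = None,
) -> list[SteppingBout]:
    """Reconstruct continuous stepping bouts from minute epochs.

    A bout core is a maximal run of consecutive grid epochs each with stepping
    seconds ≥ ``min_epoch_stepping_s``.  With ``extend_partial_edges`` the
    epochs immediately before/after a core that contain some stepping (but
    below the threshold) contribute their seconds too — a walk that starts
    mid-epoch is otherwise truncated.  A partial epoch wedged between two
    cores attaches to neither (the pause breaks continuity).  Bout duration is
    the summed stepping seconds of its epochs.

    ``mode="event_stream"`` passes an externally supplied event-level bout
    list through unchanged.
    """
    if mode == "event_stream":
        if event_bouts is None:
            raise ConfigError("event_stream mode requires event_bouts")
        return sorted(event_bouts, key=lambda b: b.start)
    if mode != "epoch_reconstruction":
        raise ConfigError(f"unknown bout extraction mode {mode!r}")

    idx = table.epoch_start
    stepping = table.data["stepping"].to_numpy(dtype=float)
    n = len(stepping)
    consecutive = np.zeros(n, dtype=bool)
    if n > 1:
        consecutive[1:] = np.diff(idx.asi8) == 60_000_000_000

    core = stepping >= min_epoch_stepping_s
    bouts: list[SteppingBout] = []
    i = 0
    while i < n:
        if not core[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and consecutive[j + 1] and core[j + 1]:
            j += 1
        lo, hi, dur = i, j, float(stepping[i : j + 1].sum())
        if extend_partial_edges:
            k = i - 1
            if k >= 0 and consecutive[i] and 0 < stepping[k] < min_epoch_stepping_s:
                # do not claim an epoch adjacent to another core run
                if not (k - 1 >= 0 and consecutive[k] and core[k - 1]):
                    lo, dur = k, dur + float(stepping[k])
            k = j + 1
            if k < n and consecutive[k] and 0 < stepping[k] < min_epoch_stepping_s:
                if not (k + 1 < n and consecutive[k + 1] and core[k + 1]):
                    hi, dur = k, dur + float(stepping[k])
        bouts.append(SteppingBout(start=idx[lo], duration=dur))
        i = hi + 1
    return bouts


def attach_heading(
    bouts: list[SteppingBout],
    heading: pd.DataFrame,
    straight_s: float = 25.0,
) -> list[SteppingBout]:
    """Annotate bouts with the straightest sub-segment's cumulative turn.

    ``heading`` has columns ``time`` and ``heading_deg``.  For each bout
    longer than ``straight_s`` the heading is interpolated to a 1-s grid over
    the bout, unwrapped, and the minimum over all ``straight_s`` windows of
    the total turning (sum of |Δheading|) is stored as ``heading_span``.
    """
    t = pd.to_datetime(heading["time"]).astype("int64").to_numpy() / 1e9
    h = np.unwrap(np.deg2rad(heading["heading_deg"].to_numpy(dtype=float)))
    w = int(round(straight_s))
    out = []
    for b in bouts:
        span = None
        if b.duration > straight_s:
            t0 = b.start.value / 1e9
            grid = t0 + np.arange(int(b.duration) + 1)
            hg = np.interp(grid, t, h)
            turn = np.abs(np.diff(hg))
            csum = np.concatenate(([0.0], np.cumsum(turn)))
            window_turn = csum[w:] - csum[:-w]
            if len(window_turn):
                span = float(np.rad2deg(window_turn.min()))
        out.append(
            SteppingBout(
                start=b.start, duration=b.duration, source=b.source, heading_span=span
            )
        )
    return out


def detect_transitions(
    bouts: list[SteppingBout],
    long_s: float = 60.0,
    straight_s: float = 25.0,
    straight_max_turn_deg: float = 30.0,
) -> list[TransitionEvent]:
    """Transition events: one per bout continuously stepping for more than
    ``long_s`` seconds, or whose straightest ``straight_s`` sub-segment turns
    no more than ``straight_max_turn_deg`` (heading optional — bouts without
    ``heading_span`` are judged on duration alone)."""
    events: list[TransitionEvent] = []
    for b in bouts:
        if b.duration > long_s:
            events.append(TransitionEvent(time=b.start, rule=LONG_BOUT))
        elif (
            b.heading_span is not None
            and b.duration > straight_s
            and b.heading_span <= straight_max_turn_deg
        ):
            events.append(TransitionEvent(time=b.start, rule=STRAIGHT_LINE))
    return events


def detect_sleep(
    labels: pd.Series,
    min_sleep_hours: float = 3.0,
    interruption_tolerance_min: float = 15.0,
) -> list[SleepPeriod]:
    """Sleep periods: runs of dominant ``primary_lying`` epochs.

    Runs separated by no more than ``interruption_tolerance_min`` minutes
    (brief toilet breaks, position checks) are merged; merged runs shorter
    than ``min_sleep_hours`` are dropped.  ``labels`` is the output of
    :func:`label_dominant`.
    """
    idx = labels.index
    lying = labels.to_numpy() == "primary_lying"
    runs: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    i, n = 0, len(lying)
    while i < n:
        if not lying[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and lying[j + 1] and (idx[j + 1] - idx[j]) == pd.Timedelta(minutes=1):
            j += 1
        runs.append((idx[i], idx[j] + pd.Timedelta(minutes=1)))
        i = j + 1

    merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    tol = pd.Timedelta(minutes=interruption_tolerance_min)
    for start, end in runs:
        if merged and start - merged[-1][1] <= tol:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    min_dur = pd.Timedelta(hours=min_sleep_hours)
    return [SleepPeriod(start=s, end=e) for s, e in merged if e - s >= min_dur]


def _clip_hours(
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]],
    day_start: pd.Timestamp,
    day_end: pd.Timestamp,
) -> tuple[float, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    clipped = []
    total = 0.0
    for a, b in intervals:
        lo, hi = max(a, day_start), min(b, day_end)
        if hi > lo:
            clipped.append((lo, hi))
            total += (hi - lo).total_seconds() / 3600.0
    return total, clipped


def classify_home_away(
    transitions: list[TransitionEvent],
    sleep: list[SleepPeriod],
    table: BehaviourEpochTable,
    mode: str = "toggle",
    min_observed_hours: float = 20.0,
) -> list[DailyParticipation]:
    """Per-day home/away classification anchored to sleep.

    For each midnight-to-midnight day the waking window runs from the end of
    the morning sleep to the start of the evening sleep.  In ``toggle`` mode
    transition events within the window alternate the state home→away→home…;
    the first is the leaving-home anchor and the last the returning-home
    anchor, so an odd transition count closes the final away interval at the
    returning anchor (yielding no extra away time).  In ``anchors`` mode the
    whole span first→last transition is reported as away ("active hours").

    ``observed_hours`` counts monitor-on-body time (epochs present, excluding
    their non-wear seconds); a day is valid iff it exceeds
    ``min_observed_hours``.  Days lacking a sleep anchor are returned with
    ``away_hours = nan`` and a ``reason``.
    """
    if mode not in {"toggle", "anchors"}:
        raise ConfigError(f"unknown home/away mode {mode!r}")
    df = table.data
    dates = sorted(set(df.index.normalize()))
    ev_times = sorted(e.time for e in transitions)
    out: list[DailyParticipation] = []
    for day in dates:
        day_start, day_end = day, day + pd.Timedelta(days=1)
        sel = (df.index >= day_start) & (df.index < day_end)
        observed_hours = float(
            (60.0 - df.loc[sel, "non_wear"].to_numpy(dtype=float)).sum() / 3600.0
        )
        valid = observed_hours > min_observed_hours

        wake_cands = [s.end for s in sleep if day_start <= s.end < day_start + pd.Timedelta(hours=14)]
        bed_cands = [
            s.start
            for s in sleep
            if day_start + pd.Timedelta(hours=12) <= s.start < day_end + pd.Timedelta(hours=6)
        ]
        if not wake_cands or not bed_cands:
            out.append(
                DailyParticipation(
                    date=day,
                    away_hours=float("nan"),
                    observed_hours=observed_hours,
                    valid=valid,
                    reason="no_sleep_anchor",
                )
            )
            continue
        wake, bed = max(wake_cands), min(bed_cands)
        evs = [t for t in ev_times if wake <= t < bed]

        if mode == "anchors":
            intervals = [(evs[0], evs[-1])] if len(evs) >= 2 else []
        else:
            intervals = [(evs[i], evs[i + 1]) for i in range(0, len(evs) - 1, 2)]
        away_hours, clipped = _clip_hours(intervals, day_start, day_end)
        out.append(
            DailyParticipation(
                date=day,
                away_hours=away_hours,
                observed_hours=observed_hours,
                valid=valid,
                away_intervals=clipped,
            )
        )
    return out


def participation_frame(days: list[DailyParticipation]) -> pd.DataFrame:
    """Flatten daily participation records into a DataFrame."""
    return pd.DataFrame(
        {
            "date": [d.date for d in days],
            "away_hours": [d.away_hours for d in days],
            "observed_hours": [d.observed_hours for d in days],
            "valid": [d.valid for d in days],
            "reason": [d.reason for d in days],
        }
    )
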