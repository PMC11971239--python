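"""Synthetic free-living cohorts with known ground truth.

The generator emulates the behavioural structure the analysis pipeline
assumes: each participant-day has one main overnight sleep, a small number of
away-from-home excursions whose boundaries are marked by sustained transition
walks, prosthesis wear intervals correlated with excursions (a don shortly
before leaving, a doff shortly after returning, plus at-home wear blocks that
top daily wear time up towards a group target), and stepping scattered through
the day in sub-minute snatches that can never masquerade as a transition walk.

From the truth schedule two sensor streams are rendered:

* a 50 Hz wrist signal — static gravity plus sub-dead-band noise while the
  prosthesis is doffed; orientation shifts, periodic movement bursts in the
  gait frequency band, and arm-swing during stepping while worn — so the
  count-emulation and non-wear stages are exercised end to end, not bypassed;
* a thigh behaviour-epoch table with per-class seconds and step counts that
  conserve each bout's cadence × duration.

All randomness flows from a single seed through per-participant child seeds,
so identical configurations reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import GenerationError
from .io_formats import ACTIVITY_CLASSES, BehaviourEpochTable, RawTriaxialRecording

PREVIOUS_USER = "previous_user"
NEW_USER = "new_user"

_NS_MIN = 60_000_000_000


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate a small free-living monitoring block: eight participants
    (half entering with prosthesis experience), seven days each, one overnight
    sleep per day, about two away-from-home excursions per day bounded by
    3-minute transition walks, and group wear-time targets loosely imitating
    experienced (~10.6 h/day) versus first-time (~4.5 h/day) users.  These are
    configuration, not measured study values.
    """

    n_participants: int = 8
    n_days: int = 7
    seed: int = 0
    start_date: str = "2025-03-03"
    previous_user_fraction: float = 0.5
    wear_hours_mean: dict = field(
        default_factory=lambda: {PREVIOUS_USER: 10.6, NEW_USER: 4.5}
    )
    wear_hours_sd: float = 1.5
    don_at_departure_prob: float = 1.0
    excursions_per_day: float = 2.0
    excursion_duration_min_mean: float = 100.0
    excursion_duration_min_sd: float = 40.0
    excursion_gap_min: float = 125.0
    sleep_onset: str = "22:30"
    sleep_onset_jitter_min: float = 25.0
    sleep_duration_h: float = 8.0
    sleep_duration_jitter_min: float = 25.0
    transition_walk_s: int = 180
    walk_cadence_spm: tuple = (95.0, 115.0)
    home_stepping_per_h: float = 2.0
    community_stepping_per_h: float = 8.0
    scatter_step_s: tuple = (20, 45)
    noise_sigma_g: float = 0.003
    burst_amplitude_g: float = 0.7
    burst_freq_hz: float = 2.0
    burst_interval_min: float = 12.0
    wrist_rate_hz: float = 50.0
    device_range_g: float = 16.0
    low_coverage_day_prob: float = 0.0
    low_coverage_missing_h: float = 5.0
    min_wear_gap_min: float = 70.0  # keeps intended non-wear ≥ the detector run

    def __post_init__(self) -> None:
        if not (0.0 <= self.don_at_departure_prob <= 1.0):
            raise GenerationError("don_at_departure_prob must lie in [0, 1]")
        if not (0.0 <= self.previous_user_fraction <= 1.0):
            raise GenerationError("previous_user_fraction must lie in [0, 1]")
        if not (0.0 <= self.low_coverage_day_prob <= 1.0):
            raise GenerationError("low_coverage_day_prob must lie in [0, 1]")
        for name in (
            "n_participants", "n_days", "excursions_per_day",
            "excursion_duration_min_mean", "sleep_duration_h",
            "transition_walk_s", "wrist_rate_hz", "burst_freq_hz",
        ):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if self.noise_sigma_g < 0 or self.burst_amplitude_g <= 0:
            raise GenerationError("signal amplitudes must be positive")
        mean_exc_h = self.excursion_duration_min_mean / 60.0
        if self.excursions_per_day * mean_exc_h > 24 - self.sleep_duration_h - 2:
            raise GenerationError("expected excursion time exceeds waking hours")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SteppingTruth:
    """One continuous stepping bout of the truth schedule."""

    start: pd.Timestamp
    duration_s: int
    cadence_spm: float

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(seconds=self.duration_s)

    @property
    def steps(self) -> int:
        return int(round(self.cadence_spm * self.duration_s / 60.0))


@dataclass
class DayTruth:
    date: pd.Timestamp
    sleep_end_morning: pd.Timestamp
    sleep_start_evening: pd.Timestamp
    excursions: list  # [(depart, return)]
    missing_intervals: list = field(default_factory=list)


@dataclass
class TruthSchedule:
    """Ground truth for one participant's monitoring block."""

    participant_id: str
    group: str
    seed: int
    start: pd.Timestamp
    end: pd.Timestamp
    days: list  # [DayTruth]
    sleep_intervals: list  # [(start, end)] clipped to the block
    wear_intervals: list  # [(don, doff)] sorted, non-overlapping
    stepping_bouts: list  # [SteppingTruth]

    def don_times(self) -> list[pd.Timestamp]:
        return [a for a, _ in self.wear_intervals]

    def doff_times(self) -> list[pd.Timestamp]:
        return [b for _, b in self.wear_intervals]

    def total_steps(self) -> int:
        return sum(b.steps for b in self.stepping_bouts)

    def daily_wear_hours(self) -> pd.Series:
        return _daily_clipped_hours(self.wear_intervals, self.start, self.end)

    def daily_away_hours(self) -> pd.Series:
        exc = [e for d in self.days for e in d.excursions]
        return _daily_clipped_hours(exc, self.start, self.end)

    def validate(self, min_gap_min: float) -> None:
        """Raise GenerationError on any violated schedule invariant."""
        prev_end = None
        for a, b in self.wear_intervals:
            if b <= a:
                raise GenerationError("empty wear interval")
            if prev_end is not None and (a - prev_end) < pd.Timedelta(minutes=min_gap_min):
                raise GenerationError("wear gap below the non-wear detector run length")
            prev_end = b
        for day in self.days:
            prev = None
            for dep, ret in day.excursions:
                if ret <= dep:
                    raise GenerationError("empty excursion")
                if prev is not None and dep <= prev:
                    raise GenerationError("overlapping excursions")
                prev = ret
                walks = [
                    s for s in self.stepping_bouts
                    if s.duration_s > 60 and (abs((s.start - dep).total_seconds()) < 1
                                              or abs((s.end - ret).total_seconds()) < 1)
                ]
                if len(walks) < 2:
                    raise GenerationError("excursion boundary lacks a transition walk")


def _daily_clipped_hours(intervals, start, end) -> pd.Series:
    days = pd.date_range(start.normalize(), end.normalize() - pd.Timedelta(days=1), freq="D")
    out = pd.Series(0.0, index=days)
    for a, b in intervals:
        for day in days:
            lo, hi = max(a, day), min(b, day + pd.Timedelta(days=1))
            if hi > lo:
                out[day] += (hi - lo).total_seconds() / 3600.0
    return out


def _ts(base: pd.Timestamp, seconds: float) -> pd.Timestamp:
    return base + pd.Timedelta(seconds=int(round(seconds)))


def simulate_truth(config: CohortConfig) -> list[TruthSchedule]:
    """Generate the cohort's truth schedules (reproducible from the seed)."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_participants)
    n_prev = int(round(config.n_participants * config.previous_user_fraction))
    schedules = []
    for i, child in enumerate(children):
        group = PREVIOUS_USER if i < n_prev else NEW_USER
        pid = f"P{i + 1}"
        schedules.append(_simulate_participant(pid, group, child, config))
    return schedules


def _simulate_participant(pid, group, seedseq, config: CohortConfig) -> TruthSchedule:
    rng = np.random.default_rng(seedseq)
    start = pd.Timestamp(config.start_date)
    end = start + pd.Timedelta(days=config.n_days)
    onset_clock = pd.Timedelta(config.sleep_onset + ":00")

    # one overnight sleep per night, clipped to the block
    sleep_raw = []
    for night in range(-1, config.n_days):
        onset = (
            start
            + pd.Timedelta(days=night)
            + onset_clock
            + pd.Timedelta(minutes=float(rng.normal(0, config.sleep_onset_jitter_min)))
        )
        dur_s = config.sleep_duration_h * 3600 + rng.normal(
            0, config.sleep_duration_jitter_min * 60
        )
        sleep_raw.append((onset.round("s"), _ts(onset.round("s"), dur_s)))
    sleep_intervals = [
        (max(a, start), min(b, end)) for a, b in sleep_raw if min(b, end) > max(a, start)
    ]

    days: list[DayTruth] = []
    wear: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    bouts: list[SteppingTruth] = []
    walk = pd.Timedelta(seconds=config.transition_walk_s)
    for d in range(config.n_days):
        day = start + pd.Timedelta(days=d)
        w_start = min(sleep_raw[d][1], end)  # morning wake (night index d = night d-1)
        w_end = sleep_raw[d + 1][0]  # evening sleep onset
        if w_end - w_start < pd.Timedelta(hours=4):
            raise GenerationError(f"{pid} day {d}: waking window shorter than 4 h")

        excursions = _place_excursions(rng, w_start, w_end, config)
        day_wear = _wear_intervals_for_day(rng, group, w_start, w_end, excursions, config)
        wear.extend(day_wear)
        bouts.extend(_stepping_for_day(rng, w_start, w_end, excursions, config))

        missing = []
        if rng.random() < config.low_coverage_day_prob:
            m0 = day + pd.Timedelta(hours=10)
            missing.append((m0, m0 + pd.Timedelta(hours=config.low_coverage_missing_h)))
        days.append(
            DayTruth(
                date=day,
                sleep_end_morning=w_start,
                sleep_start_evening=min(w_end, end),
                excursions=excursions,
                missing_intervals=missing,
            )
        )

    bouts.sort(key=lambda b: b.start)
    wear.sort()
    truth = TruthSchedule(
        participant_id=pid,
        group=group,
        seed=config.seed,
        start=start,
        end=end,
        days=days,
        sleep_intervals=sleep_intervals,
        wear_intervals=_merge_intervals(wear, pd.Timedelta(minutes=config.min_wear_gap_min)),
        stepping_bouts=bouts,
    )
    truth.validate(min_gap_min=60.0)
    return truth


def _place_excursions(rng, w_start, w_end, config):
    k = min(int(rng.poisson(config.excursions_per_day)), 4)
    placed: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    gap = pd.Timedelta(minutes=config.excursion_gap_min)
    lead = pd.Timedelta(minutes=45)  # settle-in after waking
    tail = pd.Timedelta(minutes=65)  # margin before bed (doff lag + sleep gap)
    for _ in range(k):
        dur_min = float(
            np.clip(
                rng.normal(config.excursion_duration_min_mean, config.excursion_duration_min_sd),
                45,
                240,
            )
        )
        dur = pd.Timedelta(minutes=int(round(dur_min)))
        span = (w_end - tail - dur) - (w_start + lead)
        if span <= pd.Timedelta(0):
            continue
        for _attempt in range(25):
            t0 = _ts(w_start + lead, rng.uniform(0, span.total_seconds()))
            t1 = t0 + dur
            if all(t1 + gap <= a or b + gap <= t0 for a, b in placed):
                placed.append((t0, t1))
                break
    return sorted(placed)


def _wear_intervals_for_day(rng, group, w_start, w_end, excursions, config):
    """Excursion-locked wear plus at-home blocks approaching the group target."""
    intervals = []
    for dep, ret in excursions:
        if rng.random() < config.don_at_departure_prob:
            don = _ts(dep, -60 * rng.uniform(3, 10))
            doff = _ts(ret, 60 * rng.uniform(5, 30))
        else:  # prosthesis already on well before leaving
            don = _ts(dep, -60 * rng.uniform(45, 150))
            doff = _ts(ret, 60 * rng.uniform(30, 120))
        intervals.append((max(don, w_start + pd.Timedelta(minutes=5)),
                          min(doff, w_end - pd.Timedelta(minutes=5))))
    intervals.sort()

    target_h = float(
        np.clip(rng.normal(config.wear_hours_mean[group], config.wear_hours_sd), 1.0, 15.0)
    )
    total_h = sum((b - a).total_seconds() for a, b in intervals) / 3600.0
    margin = pd.Timedelta(minutes=config.min_wear_gap_min + 5)
    edge = pd.Timedelta(minutes=5)

    # free slots between sleep edges and existing wear intervals
    def free_slots(current):
        bounds = [w_start] + [t for ab in current for t in ab] + [w_end]
        slots = []
        for j in range(0, len(bounds), 2):
            lo, hi = bounds[j], bounds[j + 1]
            lo2 = lo + (margin if j > 0 else edge)
            hi2 = hi - (margin if j + 1 < len(bounds) - 1 else edge)
            if hi2 > lo2:
                slots.append((lo2, hi2))
        return sorted(slots, key=lambda s: s[0] - s[1])  # longest first

    remaining = target_h - total_h
    while remaining > 0.5:
        slots = free_slots(intervals)
        if not slots:
            break
        lo, hi = slots[0]
        cap_h = (hi - lo).total_seconds() / 3600.0
        if cap_h < 0.5:
            break
        block_h = min(remaining, cap_h)
        off = rng.uniform(0, max(cap_h - block_h, 0))
        a = _ts(lo, off * 3600)
        b = _ts(a, block_h * 3600)
        intervals = sorted(intervals + [(a, b)])
        remaining -= block_h
    return _merge_intervals(intervals, pd.Timedelta(minutes=config.min_wear_gap_min))


def _merge_intervals(intervals, min_gap):
    merged = []
    for a, b in sorted(intervals):
        if merged and a - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], max(b, merged[-1][1]))
        else:
            merged.append((a, b))
    return merged


def _stepping_for_day(rng, w_start, w_end, excursions, config):
    """Transition walks at excursion boundaries plus scattered sub-minute stepping."""
    bouts = []
    walk_s = int(config.transition_walk_s)
    blocked = set()  # minute epochs already hosting stepping (plus guard bands)

    def block(t0, t1, guard=1):
        e0 = t0.value // _NS_MIN - guard
        e1 = t1.value // _NS_MIN + guard
        blocked.update(range(e0, e1 + 1))

    for dep, ret in excursions:
        cad = rng.uniform(*config.walk_cadence_spm)
        bouts.append(SteppingTruth(start=dep, duration_s=walk_s, cadence_spm=cad))
        ret_walk = ret - pd.Timedelta(seconds=walk_s)
        bouts.append(
            SteppingTruth(start=ret_walk, duration_s=walk_s,
                          cadence_spm=rng.uniform(*config.walk_cadence_spm))
        )
        block(dep, dep + pd.Timedelta(seconds=walk_s))
        block(ret_walk, ret)

    def scatter(lo, hi, rate_per_h):
        span_h = (hi - lo).total_seconds() / 3600.0
        if span_h <= 0:
            return
        n = rng.poisson(rate_per_h * span_h)
        e_lo, e_hi = lo.value // _NS_MIN + 1, hi.value // _NS_MIN - 1
        cands = [e for e in range(e_lo, e_hi) if e not in blocked]
        if not cands or n == 0:
            return
        chosen = rng.choice(len(cands), size=min(n, len(cands)), replace=False)
        for c in np.sort(chosen):
            epoch = cands[int(c)]
            dur = int(rng.integers(config.scatter_step_s[0], config.scatter_step_s[1] + 1))
            off = int(rng.integers(0, 60 - dur + 1))
            t0 = pd.Timestamp((epoch * 60 + off) * 1_000_000_000)
            bouts.append(
                SteppingTruth(start=t0, duration_s=dur,
                              cadence_spm=rng.uniform(80, 110))
            )
            blocked.add(epoch)

    walk_td = pd.Timedelta(seconds=walk_s + 120)
    cursor = w_start
    for dep, ret in excursions:
        scatter(cursor, dep, config.home_stepping_per_h)  # at home
        scatter(dep + walk_td, ret - walk_td, config.community_stepping_per_h)
        cursor = ret
    scatter(cursor, w_end, config.home_stepping_per_h)
    return bouts


# ---------------------------------------------------------------------------
# renderers


def render_wrist(truth: TruthSchedule, config: CohortConfig) -> RawTriaxialRecording:
    """Render the 50 Hz wrist signal implied by a truth schedule.

    Doffed: fixed gravity orientation plus Gaussian noise whose filtered
    amplitude stays far below the count dead-band.  Worn: a different static
    orientation, movement bursts in the gait band at the start and end of each
    wear interval and at least every ``burst_interval_min`` in between, and
    arm-swing oscillation during stepping bouts.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(truth.participant_id[1:]), 7])
    )
    fs = config.wrist_rate_hz
    n = int(round((truth.end - truth.start).total_seconds() * fs))
    a = rng.standard_normal((n, 3), dtype=np.float32) * np.float32(config.noise_sigma_g)
    a[:, 2] += 1.0  # doffed: resting flat, gravity on z

    def sidx(t: pd.Timestamp) -> int:
        return int(round((t - truth.start).total_seconds() * fs))

    for don, doff in truth.wear_intervals:
        i0, i1 = max(sidx(don), 0), min(sidx(doff), n)
        # worn orientation: gravity shared between x and z
        a[i0:i1, 0] += 0.64
        a[i0:i1, 2] -= 0.23

        # movement bursts: at don, at least every burst_interval, and before doff
        t = 0.0
        span = (doff - don).total_seconds()
        starts = []
        while t < span - 25:
            starts.append(t)
            t += rng.uniform(4 * 60, config.burst_interval_min * 60)
        starts.append(max(span - 22, 0.0))
        for s in starts:
            dur = rng.uniform(8, 15)
            j0 = i0 + int(s * fs)
            j1 = min(j0 + int(dur * fs), i1)
            if j1 <= j0:
                continue
            tt = np.arange(j1 - j0, dtype=np.float32) / np.float32(fs)
            a[j0:j1, 0] += np.float32(config.burst_amplitude_g) * np.sin(
                2 * np.pi * np.float32(config.burst_freq_hz) * tt
            )

    # arm swing while stepping with the prosthesis on
    for bout in truth.stepping_bouts:
        for don, doff in truth.wear_intervals:
            lo, hi = max(bout.start, don), min(bout.end, doff)
            if hi <= lo:
                continue
            j0, j1 = sidx(lo), min(sidx(hi), n)
            tt = np.arange(j1 - j0, dtype=np.float32) / np.float32(fs)
            a[j0:j1, 1] += np.float32(0.45) * np.sin(
                2 * np.pi * np.float32(1.9) * tt
            )

    np.clip(a, -config.device_range_g, config.device_range_g, out=a)
    return RawTriaxialRecording(
        start_time=truth.start,
        rate=fs,
        samples=a,
        device_range=config.device_range_g,
        participant_id=truth.participant_id,
    )


def render_thigh(truth: TruthSchedule, config: CohortConfig) -> BehaviourEpochTable:
    """Render the thigh monitor's per-minute behaviour table.

    Sleep maps to primary lying, stepping bouts to stepping seconds with steps
    conserving each bout's cadence × duration (largest-remainder allocation),
    and the rest of each epoch is a sedentary/upright filler mix.  Epochs in a
    day's missing intervals are dropped, not zero-filled.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(truth.participant_id[1:]), 11])
    )
    grid = pd.date_range(truth.start, truth.end, freq="60s", inclusive="left")
    n = len(grid)
    g0 = grid[0].value // _NS_MIN
    secs = {c: np.zeros(n, dtype=np.int64) for c in ACTIVITY_CLASSES}
    steps = np.zeros(n, dtype=np.int64)

    def overlap_seconds(a: pd.Timestamp, b: pd.Timestamp) -> list[tuple[int, int]]:
        """(epoch index, whole seconds of [a,b) within it)."""
        out = []
        e0, e1 = a.value // _NS_MIN, (b.value - 1) // _NS_MIN
        for e in range(max(e0, g0), min(e1, g0 + n - 1) + 1):
            lo = max(a.value, e * _NS_MIN)
            hi = min(b.value, (e + 1) * _NS_MIN)
            out.append((e - g0, int(round((hi - lo) / 1e9))))
        return out

    for a, b in truth.sleep_intervals:
        for idx, s in overlap_seconds(a, b):
            secs["primary_lying"][idx] += s

    for bout in truth.stepping_bouts:
        parts = overlap_seconds(bout.start, bout.end)
        total = bout.steps
        dur = sum(s for _, s in parts)
        cum_prev, acc = 0, 0
        for idx, s in parts:
            acc += s
            alloc = int(round(total * acc / dur)) - cum_prev
            cum_prev += alloc
            secs["stepping"][idx] += s
            steps[idx] += alloc

    used = secs["primary_lying"] + secs["stepping"]
    if (used > 60).any():
        raise GenerationError("schedule over-fills an epoch (sleep/stepping overlap)")
    rem = 60 - used
    sed_frac = rng.uniform(0.55, 0.85, size=n)
    sed = np.round(rem * sed_frac).astype(np.int64)
    secs["sedentary"] = sed
    secs["upright"] = rem - sed

    df = pd.DataFrame({c: secs[c] for c in ACTIVITY_CLASSES}, index=grid)
    df["steps"] = steps
    df.index.name = "epoch_start"

    missing = [iv for d in truth.days for iv in d.missing_intervals]
    if missing:
        keep = np.ones(n, dtype=bool)
        for a, b in missing:
            keep &= ~((grid >= a) & (grid < b))
        df = df[keep]
    return BehaviourEpochTable(df)


# ---------------------------------------------------------------------------
# truth-versus-estimate utilities


def match_events(
    truth_times: list[pd.Timestamp],
    detected_times: list[pd.Timestamp],
    tol_s: float = 120.0,
) -> float:
    """Fraction of truth events matched one-to-one within ± ``tol_s``."""
    if not truth_times:
        return 1.0
    detected = sorted(detected_times)
    used = np.zeros(len(detected), dtype=bool)
    hits = 0
    for t in sorted(truth_times):
        best, best_d = None, tol_s
        for j, d in enumerate(detected):
            if used[j]:
                continue
            delta = abs((d - t).total_seconds())
            if delta <= best_d:
                best, best_d = j, delta
        if best is not None:
            used[best] = True
            hits += 1
    return hits / len(truth_times)


def interval_jaccard(
    a: list[tuple[pd.Timestamp, pd.Timestamp]],
    b: list[tuple[pd.Timestamp, pd.Timestamp]],
) -> float:
    """Jaccard overlap of two interval unions (1.0 when both are empty)."""
    def to_arr(iv):
        return [(x.value, y.value) for x, y in iv]

    def union_len(iv):
        total, last = 0, None
        for x, y in sorted(iv):
            if last is None or x > last:
                total += y - x
                last = y
            elif y > last:
                total += y - last
                last = y
        return total

    av, bv = to_arr(a), to_arr(b)
    inter = 0
    for x1, y1 in av:
        for x2, y2 in bv:
            inter += max(0, min(y1, y2) - max(x1, x2))
    un = union_len(av + bv)
    return 1.0 if un == 0 else inter / un
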