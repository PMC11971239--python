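"""Fuse the wrist wear stream and the thigh behaviour stream on one clock.

The two monitors run on independent internal clocks; a bench-assessed offset
(thigh clock minus wrist clock, seconds) is applied from configuration before
the streams are snapped to the wrist's minute grid.  The fused product is the
amount of stepping in the 30 minutes before and after every prosthesis
donning/doffing event — a direct read-out of whether putting the prosthesis on
is tied to going out and being active.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behaviour import label_dominant
from .errors import AlignmentError, ConfigError
from .io_formats import BehaviourEpochTable
from .wear import DonDoffEvent, WearMask


@dataclass
class AlignedStreams:
    """Wear mask and behaviour table on a common epoch grid."""

    wear: WearMask
    behaviour: BehaviourEpochTable
    applied_offset: float  # s, thigh clock minus wrist clock
    overlap: tuple[pd.Timestamp, pd.Timestamp]  # [start, end) of joint coverage


@dataclass
class EventWindowStats:
    """Stepping minutes in the ±window around one don/doff event."""

    event: DonDoffEvent
    pre_stepping_min: float
    post_stepping_min: float
    complete: bool


def align_streams(
    wear: WearMask,
    behaviour: BehaviourEpochTable,
    offset_s: float = 0.0,
) -> AlignedStreams:
    """Shift thigh timestamps by −offset and snap them to the wrist grid.

    ``offset_s`` is the thigh clock minus the wrist clock, so subtracting it
    expresses thigh epochs in wrist time.  Raises
    :class:`~limbwear.errors.AlignmentError` when the streams share no epoch.
    """
    shifted = behaviour.data.copy()
    idx = behaviour.epoch_start - pd.Timedelta(seconds=offset_s)
    shifted.index = pd.DatetimeIndex(idx.round("60s"), name="epoch_start")
    if shifted.index.has_duplicates:
        raise AlignmentError("offset snapping collapsed distinct thigh epochs")
    aligned = BehaviourEpochTable(shifted)

    if len(wear) == 0 or len(aligned) == 0:
        raise AlignmentError("cannot align an empty stream")
    start = max(wear.epoch_start[0], aligned.epoch_start[0])
    end = min(
        wear.epoch_start[-1] + pd.Timedelta(minutes=1),
        aligned.epoch_start[-1] + pd.Timedelta(minutes=1),
    )
    if end <= start:
        raise AlignmentError(
            f"no overlap between streams ({wear.epoch_start[0]}–{wear.epoch_start[-1]}"
            f" vs {aligned.epoch_start[0]}–{aligned.epoch_start[-1]})"
        )
    return AlignedStreams(wear=wear, behaviour=aligned, applied_offset=offset_s, overlap=(start, end))


def estimate_clock_offset(
    vm_series: pd.Series,
    behaviour: BehaviourEpochTable,
    max_lag_min: int = 15,
) -> float:
    """Advisory cross-correlation estimate of the thigh−wrist clock lag (s).

    Correlates per-minute wrist count vector magnitude with thigh steps per
    minute over integer-minute lags.  The estimate is reported for inspection
    only and is never applied automatically.
    """
    joint = pd.DataFrame({"vm": vm_series}).join(
        behaviour.data["steps"], how="inner"
    )
    if len(joint) < 3:
        raise AlignmentError("too little joint coverage to estimate an offset")
    vm = joint["vm"].to_numpy(dtype=float)
    steps = joint["steps"].to_numpy(dtype=float)
    vm = vm - vm.mean()
    steps = steps - steps.mean()
    best_lag, best_corr = 0, -np.inf
    for lag in range(-max_lag_min, max_lag_min + 1):
        if lag >= 0:
            a, b = vm[lag:], steps[: len(steps) - lag]
        else:
            a, b = vm[:lag], steps[-lag:]
        if len(a) < 3:
            continue
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        corr = float((a * b).sum() / denom) if denom > 0 else 0.0
        if corr > best_corr:
            best_lag, best_corr = lag, corr
    return float(best_lag * 60)


def stepping_around_events(
    aligned: AlignedStreams,
    events: Sequence[DonDoffEvent],
    window_min: int = 30,
    epoch_rule: str = "any_stepping",
) -> list[EventWindowStats]:
    """Stepping epochs in the ±``window_min`` windows around each event.

    ``pre`` counts qualifying epochs starting in [t − window, t) and ``post``
    in [t, t + window): the epoch beginning at the event instant belongs to
    the post-event side.  ``epoch_rule`` is ``any_stepping`` (stepping
    seconds > 0 — an epoch "during which the participant was stepping") or
    ``dominant_stepping`` (stepping is the dominant class).  A window is
    ``complete`` only if every epoch on both sides is present, free of
    monitor non-wear, inside the aligned overlap, and no event of the
    opposite kind falls within it; incomplete windows are flagged and
    excluded from group means rather than silently averaged.
    """
    if epoch_rule == "any_stepping":
        qualifies = aligned.behaviour.data["stepping"].to_numpy(dtype=float) > 0
    elif epoch_rule == "dominant_stepping":
        qualifies = label_dominant(aligned.behaviour).to_numpy() == "stepping"
    else:
        raise ConfigError(f"unknown epoch_rule {epoch_rule!r}")
    df = aligned.behaviour.data
    step_flags = pd.Series(qualifies, index=df.index)
    nonwear_s = df["non_wear"]
    window = pd.Timedelta(minutes=window_min)
    ov_start, ov_end = aligned.overlap
    times = [e.time for e in events]

    out: list[EventWindowStats] = []
    for e in events:
        pre_sel = (df.index >= e.time - window) & (df.index < e.time)
        post_sel = (df.index >= e.time) & (df.index < e.time + window)
        pre = float(step_flags[pre_sel].sum())
        post = float(step_flags[post_sel].sum())
        n_expected = int(window_min)
        complete = (
            int(pre_sel.sum()) == n_expected
            and int(post_sel.sum()) == n_expected
            and float(nonwear_s[pre_sel | post_sel].sum()) == 0.0
            and e.time - window >= ov_start
            and e.time + window <= ov_end
            and not any(
                t != e.time and abs((t - e.time).total_seconds()) < window_min * 60
                for t in times
            )
        )
        out.append(
            EventWindowStats(
                event=e, pre_stepping_min=pre, post_stepping_min=post, complete=complete
            )
        )
    return out


def aggregate_group(
    stats: Mapping[tuple[str, str], Sequence[EventWindowStats]],
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group/phase summary of pre/post-event stepping.

    ``stats`` maps (participant_id, phase) to that period's event-window
    records; ``groups`` maps participant_id to its cohort group.  Only
    complete windows enter the means.  Returns ``(per_participant, summary)``:
    the summary averages participant means (equal participant weight) per
    (group, phase, event kind) over the full grid, with empty cells reported
    as missing (NaN), never as zero.
    """
    rows = []
    for (pid, phase), recs in stats.items():
        if pid not in groups:
            raise ConfigError(f"participant {pid!r} has no group label")
        for kind in ("don", "doff"):
            sel = [r for r in recs if r.event.kind == kind and r.complete]
            rows.append(
                {
                    "participant_id": pid,
                    "phase": phase,
                    "group": groups[pid],
                    "event_kind": kind,
                    "n_events": len(sel),
                    "mean_pre_min": float(np.mean([r.pre_stepping_min for r in sel]))
                    if sel
                    else np.nan,
                    "mean_post_min": float(np.mean([r.post_stepping_min for r in sel]))
                    if sel
                    else np.nan,
                }
            )
    per_participant = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "phase", "group", "event_kind",
            "n_events", "mean_pre_min", "mean_post_min",
        ],
    )
    if per_participant.empty:
        summary = pd.DataFrame(
            columns=["group", "phase", "event_kind", "mean_pre_min",
                     "mean_post_min", "n_events", "n_participants"]
        )
        return per_participant, summary

    all_groups = sorted(set(groups.values()))
    all_phases = sorted(per_participant["phase"].unique())
    grid = pd.MultiIndex.from_product(
        [all_groups, all_phases, ["don", "doff"]], names=["group", "phase", "event_kind"]
    )
    contributing = per_participant[per_participant["n_events"] > 0]
    agg = contributing.groupby(["group", "phase", "event_kind"]).agg(
        mean_pre_min=("mean_pre_min", "mean"),
        mean_post_min=("mean_post_min", "mean"),
        n_events=("n_events", "sum"),
        n_participants=("participant_id", "nunique"),
    )
    summary = agg.reindex(grid).reset_index()
    return per_participant, summary
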