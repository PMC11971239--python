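"""End-to-end convenience driver: raw streams in, daily summaries out.

Thin orchestration over the stage modules — every step here is available
individually for scripted analyses; the CLI and the acceptance tooling both
go through this module so there is exactly one canonical stage order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import behaviour as bh
from . import counts as ct
from . import fusion as fu
from . import wear as wr
from .io_formats import BehaviourEpochTable, RawTriaxialRecording


@dataclass
class ParticipantResult:
    """All per-participant pipeline products."""

    participant_id: str
    count_series: ct.CountEpochSeries
    mask: wr.WearMask
    events: list[wr.DonDoffEvent]
    daily_wear: pd.DataFrame
    bouts: list[bh.SteppingBout]
    transitions: list[bh.TransitionEvent]
    sleep: list[bh.SleepPeriod]
    participation: list[bh.DailyParticipation]
    window_stats: list[fu.EventWindowStats]


def run_participant(
    wrist: RawTriaxialRecording,
    thigh: BehaviourEpochTable,
    *,
    count_params: ct.CountParams | None = None,
    nonwear_params: wr.NonWearParams | None = None,
    clock_offset_s: float = 0.0,
    home_away_mode: str = "toggle",
    min_observed_hours: float = 20.0,
    window_min: int = 30,
    epoch_rule: str = "any_stepping",
) -> ParticipantResult:
    """Run the full wrist + thigh pipeline for one participant."""
    series = ct.vector_magnitude(ct.emulate_counts(wrist, count_params))
    mask = wr.detect_wear(series, nonwear_params)
    events = wr.extract_events(mask)
    daily_wear = wr.daily_wear_summary(mask)

    bouts = bh.extract_stepping_bouts(thigh)
    transitions = bh.detect_transitions(bouts)
    sleep = bh.detect_sleep(bh.label_dominant(thigh))
    participation = bh.classify_home_away(
        transitions, sleep, thigh, mode=home_away_mode, min_observed_hours=min_observed_hours
    )

    aligned = fu.align_streams(mask, thigh, offset_s=clock_offset_s)
    in_overlap = [e for e in events if aligned.overlap[0] <= e.time < aligned.overlap[1]]
    window_stats = fu.stepping_around_events(
        aligned, in_overlap, window_min=window_min, epoch_rule=epoch_rule
    )
    return ParticipantResult(
        participant_id=wrist.participant_id,
        count_series=series,
        mask=mask,
        events=events,
        daily_wear=daily_wear,
        bouts=bouts,
        transitions=transitions,
        sleep=sleep,
        participation=participation,
        window_stats=window_stats,
    )
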