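"""Prosthesis wear detection from epoch-level activity counts.

The sensor sits on the prosthetic wrist, so sensor non-wear is taken as
prosthesis non-wear.  Non-wear is detected on the per-epoch count vector
magnitude with a run-length rule: an epoch is non-wear (doffed) iff it is
covered by some window that

* starts and ends on epochs with vm ≤ ``zero_threshold``,
* spans at least ``min_nonwear_run`` minutes,
* contains at most ``spike_tolerance_epochs`` interrupting epochs, each with
  vm ≤ ``spike_max_vm`` and no two of them adjacent (two consecutive active
  epochs always break a window).

This window-cover definition is order-independent: the classification does not
depend on a scan direction.  Gaps in the epoch grid are classified
``no_data`` and never contribute to (or bridge) non-wear windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountEpochSeries
from .errors import ConfigError

WORN = "worn"
DOFFED = "doffed"
NO_DATA = "no_data"

DON = "don"
DOFF = "doff"


@dataclass
class NonWearParams:
    """Parameters of the run-length non-wear rule (counts / minutes)."""

    zero_threshold: float = 0.0
    min_nonwear_run: int = 60
    spike_tolerance_epochs: int = 2
    spike_max_vm: float = 100.0

    def __post_init__(self) -> None:
        if self.min_nonwear_run < 1:
            raise ConfigError("min_nonwear_run must be ≥ 1 minute")
        if self.spike_tolerance_epochs < 0:
            raise ConfigError("spike_tolerance_epochs must be ≥ 0")
        if self.spike_max_vm < self.zero_threshold:
            raise ConfigError("spike_max_vm must be ≥ zero_threshold")


@dataclass
class WearMask:
    """Per-epoch worn/doffed/no_data state on a gap-free 60-s grid."""

    epoch_start: pd.DatetimeIndex
    state: np.ndarray  # of {"worn", "doffed", "no_data"}

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=object)
        if len(self.state) != len(self.epoch_start):
            raise ConfigError("state and epoch grid length mismatch")
        bad = set(np.unique(self.state)) - {WORN, DOFFED, NO_DATA}
        if bad:
            raise ConfigError(f"unknown wear states: {bad}")

    def __len__(self) -> int:
        return len(self.state)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch_start": self.epoch_start, "state": self.state})


@dataclass(frozen=True)
class DonDoffEvent:
    """A wear-state transition at an epoch boundary."""

    time: pd.Timestamp
    kind: str  # "don" | "doff"


def nonwear_epochs(vm: np.ndarray, observed: np.ndarray, params: NonWearParams) -> np.ndarray:
    """Boolean non-wear flags for one epoch sequence.

    Run-length-encoding implementation of the window-cover rule: sub-threshold
    runs may be chained through single-epoch spikes, and any chain long enough
    marks all its epochs (spikes included) as non-wear.
    """
    n = len(vm)
    out = np.zeros(n, dtype=bool)
    if n == 0:
        return out
    zero = (vm <= params.zero_threshold) & observed
    spike = (~zero) & (vm <= params.spike_max_vm) & observed

    # run-length encode into (kind, start, stop) blocks
    kinds = np.where(zero, 0, np.where(spike, 1, 2))
    kinds = np.where(observed, kinds, 2)  # unobserved epochs break windows
    change = np.flatnonzero(np.diff(kinds)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n]))
    blocks = [(int(kinds[a]), int(a), int(b)) for a, b in zip(starts, stops)]

    zero_idx = [i for i, (k, _, _) in enumerate(blocks) if k == 0]
    for pos, i in enumerate(zero_idx):
        # chain forward through ≤ tolerance single-epoch spike separators
        j = i
        for nxt in range(pos + 1, len(zero_idx)):
            if nxt - pos > params.spike_tolerance_epochs:
                break
            sep_ok = (
                zero_idx[nxt] - zero_idx[nxt - 1] == 2
                and blocks[zero_idx[nxt] - 1][0] == 1
                and blocks[zero_idx[nxt] - 1][2] - blocks[zero_idx[nxt] - 1][1] == 1
            )
            if not sep_ok:
                break
            j = zero_idx[nxt]
        # the longest window starting at this zero-run is blocks[i]..blocks[j]
        a, b = blocks[i][1], blocks[j][2]
        if b - a >= params.min_nonwear_run:
            out[a:b] = True
    return out


def detect_wear(series: CountEpochSeries, params: NonWearParams | None = None) -> WearMask:
    """Classify each epoch as worn / doffed / no_data.

    The mask covers the full minute grid from the first to the last epoch of
    ``series``; grid gaps become ``no_data``.
    """
    params = params or NonWearParams()
    if series.vm is None:
        raise ConfigError("vm must be populated (run vector_magnitude first)")
    if len(series) == 0:
        return WearMask(epoch_start=series.epoch_start, state=np.array([], dtype=object))

    grid = pd.date_range(series.epoch_start[0], series.epoch_start[-1], freq="60s")
    vm = np.full(len(grid), np.nan)
    pos = ((series.epoch_start.asi8 - grid[0].value) // 60_000_000_000).astype(np.int64)
    vm[pos] = series.vm
    observed = ~np.isnan(vm)
    vm_filled = np.where(observed, vm, 0.0)

    doffed = nonwear_epochs(vm_filled, observed, params)
    state = np.where(~observed, NO_DATA, np.where(doffed, DOFFED, WORN)).astype(object)
    return WearMask(epoch_start=grid, state=state)


def extract_events(mask: WearMask) -> list[DonDoffEvent]:
    """Don/doff events at worn↔doffed transitions.

    Transitions into or out of ``no_data`` (including recording start/end)
    emit no events: a 30-min behaviour window attached to an artefactual
    boundary would bias downstream summaries.
    """
    events: list[DonDoffEvent] = []
    s = mask.state
    for i in range(1, len(s)):
        prev, cur = s[i - 1], s[i]
        if prev == DOFFED and cur == WORN:
            events.append(DonDoffEvent(time=mask.epoch_start[i], kind=DON))
        elif prev == WORN and cur == DOFFED:
            events.append(DonDoffEvent(time=mask.epoch_start[i], kind=DOFF))
    return events


def daily_wear_summary(mask: WearMask) -> pd.DataFrame:
    """Per-calendar-day wear hours (midnight to midnight).

    Returns columns ``date, worn_hours, doffed_hours, observed_hours``;
    ``observed_hours`` (worn + doffed) supports valid-day filtering downstream.
    Each epoch is attributed to the day containing its start.
    """
    if len(mask) == 0:
        return pd.DataFrame(columns=["date", "worn_hours", "doffed_hours", "observed_hours"])
    df = pd.DataFrame({"date": mask.epoch_start.normalize(), "state": mask.state})
    grouped = df.groupby("date")["state"]
    worn = grouped.apply(lambda s: (s == WORN).sum() / 60.0)
    doffed = grouped.apply(lambda s: (s == DOFFED).sum() / 60.0)
    out = pd.DataFrame(
        {
            "date": worn.index,
            "worn_hours": worn.to_numpy(),
            "doffed_hours": doffed.to_numpy(),
        }
    )
    out["observed_hours"] = out["worn_hours"] + out["doffed_hours"]
    return out.reset_index(drop=True)


def mask_from_events(
    events: list[DonDoffEvent], mask_like: WearMask
) -> WearMask:
    """Reconstruct a wear mask from an event list over the observed segments.

    Inverse of :func:`extract_events` for round-trip checking: within each
    observed segment the state toggles at the listed event times, starting
    from the segment's recorded initial state.
    """
    state = np.array(mask_like.state, dtype=object)
    ev = {e.time.value: e.kind for e in events}
    out = state.copy()
    current = None
    for i, t in enumerate(mask_like.epoch_start):
        if state[i] == NO_DATA:
            current = None
            out[i] = NO_DATA
            continue
        if current is None:
            current = state[i]  # segment initial condition
        kind = ev.get(t.value)
        if kind == DON:
            current = WORN
        elif kind == DOFF:
            current = DOFFED
        out[i] = current
    return WearMask(epoch_start=mask_like.epoch_start, state=out)
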