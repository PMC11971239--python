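"""Shared test utilities: independent oracles and small data factories.

The oracles deliberately re-derive results through naive per-element loops so
they share no code path with the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from limbwear.counts import (
    BAND_PASS_A,
    BAND_PASS_B,
    FILTER_GAIN,
    CountEpochSeries,
)
from limbwear.io_formats import ACTIVITY_CLASSES, BehaviourEpochTable, RawTriaxialRecording


# ---------------------------------------------------------------------------
# count-emulation oracle: straight-loop implementation of the same chain


def oracle_counts(rec: RawTriaxialRecording, epoch_length: int = 60) -> np.ndarray:
    """Per-epoch per-axis counts via explicit per-sample loops.

    Mirrors the published chain definition (30 Hz resample, band-pass,
    10 Hz decimation, ±2.13 g clip, rectify, 0.068 g dead-band, 0.0164 g
    quantization, 1 s accumulation, minute-anchored epoch sums).  The filter
    warm-up uses a long constant pad of the first sample, which converges to
    the steady-state initial condition.
    """
    b = [float(v) for v in FILTER_GAIN * BAND_PASS_B]
    a = [float(v) for v in BAND_PASS_A]
    n = rec.n_samples
    per_axis = []
    for ax in range(3):
        x = [float(v) for v in rec.samples[:, ax]]
        dur = (n - 1) / rec.rate
        m = int(math.floor(dur * 30.0)) + 1
        xi = []
        for i in range(m):
            t = i / 30.0
            j = int(math.floor(t * rec.rate))
            if j >= n - 1:
                xi.append(x[n - 1])
            else:
                f = t * rec.rate - j
                xi.append(x[j] * (1 - f) + x[j + 1] * f)
        pad = 2000
        sig = [xi[0]] * pad + xi
        y = [0.0] * len(sig)
        for i in range(len(sig)):
            s = 0.0
            for k in range(len(b)):
                if i - k >= 0:
                    s += b[k] * sig[i - k]
            for k in range(1, len(a)):
                if i - k >= 0:
                    s -= a[k] * y[i - k]
            y[i] = s
        y = y[pad:]
        dec = y[::3]
        q = []
        for v in dec:
            v = max(-2.13, min(2.13, v))
            v = abs(v)
            if v < 0.068:
                v = 0.0
            q.append(math.floor(v / 0.0164))
        secs = [sum(q[i * 10 : (i + 1) * 10]) for i in range(len(q) // 10)]
        per_axis.append(secs)

    first = rec.start_time.ceil(f"{epoch_length}s")
    off = int(round((first - rec.start_time).total_seconds()))
    n_sec = min(len(s) for s in per_axis)
    n_ep = (n_sec - off) // epoch_length
    return np.array(
        [
            [
                sum(axis[off + e * epoch_length : off + (e + 1) * epoch_length])
                for axis in per_axis
            ]
            for e in range(n_ep)
        ],
        dtype=np.int64,
    )


# ---------------------------------------------------------------------------
# non-wear oracle: forward-maximal window from every start, union of marks


def oracle_nonwear(
    vm,
    observed,
    zero_threshold: float = 0.0,
    min_run: int = 60,
    spike_tolerance: int = 2,
    spike_max: float = 100.0,
) -> np.ndarray:
    n = len(vm)
    out = np.zeros(n, dtype=bool)
    for i in range(n):
        if not observed[i] or vm[i] > zero_threshold:
            continue
        spikes, last_was_spike, end, j = 0, False, i, i
        while j < n and observed[j]:
            if vm[j] <= zero_threshold:
                last_was_spike = False
                end = j
                j += 1
            elif vm[j] <= spike_max and spikes < spike_tolerance and not last_was_spike:
                spikes += 1
                last_was_spike = True
                j += 1
            else:
                break
        if end - i + 1 >= min_run:
            out[i : end + 1] = True
    return out


# ---------------------------------------------------------------------------
# stepping-bout oracle: naive scan with the same extension convention


def oracle_bouts(stepping_s, threshold: float = 55.0):
    """(start index, summed seconds) per bout on a contiguous minute grid."""
    n = len(stepping_s)
    core = [s >= threshold for s in stepping_s]
    bouts = []
    i = 0
    while i < n:
        if not core[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and core[j + 1]:
            j += 1
        lo, hi = i, j
        dur = sum(stepping_s[i : j + 1])
        if lo - 1 >= 0 and 0 < stepping_s[lo - 1] < threshold and not (lo - 2 >= 0 and core[lo - 2]):
            dur += stepping_s[lo - 1]
            lo -= 1
        if hi + 1 < n and 0 < stepping_s[hi + 1] < threshold and not (hi + 2 < n and core[hi + 2]):
            dur += stepping_s[hi + 1]
            hi += 1
        bouts.append((lo, dur))
        i = hi + 1
    return bouts


# ---------------------------------------------------------------------------
# factories


def make_count_series(vm_values, start="2025-01-06 00:00") -> CountEpochSeries:
    """Count series whose x-axis carries the requested vm values."""
    vm = np.asarray(vm_values, dtype=float)
    counts = np.zeros((len(vm), 3), dtype=np.int64)
    counts[:, 0] = np.round(vm).astype(np.int64)
    return CountEpochSeries(
        epoch_start=pd.date_range(start, periods=len(vm), freq="60s"),
        counts=counts,
        vm=vm,
    )


def make_behaviour_table(
    start="2025-01-06 00:00",
    n: int = 60,
    stepping=None,
    lying=None,
    non_wear=None,
    steps=None,
    drop=(),
) -> BehaviourEpochTable:
    """Behaviour table with given per-epoch stepping / lying / non-wear seconds.

    The remainder of each epoch is sedentary.  ``drop`` removes grid rows to
    create missing epochs.
    """
    idx = pd.date_range(start, periods=n, freq="60s")
    data = {c: np.zeros(n, dtype=np.int64) for c in ACTIVITY_CLASSES}
    for name, values in (("stepping", stepping), ("primary_lying", lying), ("non_wear", non_wear)):
        if values is not None:
            data[name] = np.asarray(values, dtype=np.int64)
    used = sum(data[c] for c in ACTIVITY_CLASSES if c != "sedentary")
    data["sedentary"] = 60 - used
    df = pd.DataFrame(data, index=idx)
    df["steps"] = (
        np.asarray(steps, dtype=np.int64)
        if steps is not None
        else (data["stepping"] > 0).astype(np.int64) * (df["stepping"] * 100 // 60)
    )
    df.index.name = "epoch_start"
    if drop:
        df = df.drop(index=[idx[i] for i in drop])
    return BehaviourEpochTable(df)


def sine_recording(
    freq_hz: float,
    amplitude_g: float,
    minutes: float = 3.0,
    rate: float = 50.0,
    axis: int = 0,
    start="2025-01-06 09:00",
    dc=(0.0, 0.0, 0.0),
) -> RawTriaxialRecording:
    n = int(minutes * 60 * rate)
    t = np.arange(n) / rate
    samples = np.tile(np.asarray(dc, dtype=np.float64), (n, 1))
    samples[:, axis] += amplitude_g * np.sin(2 * np.pi * freq_hz * t)
    return RawTriaxialRecording(start_time=start, rate=rate, samples=samples)
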