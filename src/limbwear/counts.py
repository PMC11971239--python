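"""ActiGraph-equivalent activity-count emulation from raw acceleration.

Legacy research accelerometers report "activity counts": the raw signal is
band-pass filtered (≈0.25–2.5 Hz, the frequency band of human movement),
clipped to the device's analogue peak, rectified, dead-banded to suppress
sensor noise, quantized at the device's ADC resolution and accumulated over
time.  A published emulation of that on-board chain lets modern raw
accelerometers (here the prosthesis-wrist sensor) be analysed with count-based
algorithms such as the non-wear detector in :mod:`limbwear.wear`.

The chain implemented here, applied per axis:

1. resample to 30 Hz (linear interpolation);
2. band-pass filter with the fixed IIR coefficient set below (a replication
   of the legacy device's 0.29–1.66 Hz movement filter);
3. decimate to 10 Hz (every 3rd sample);
4. clip to ±2.13 g, rectify, zero values below the 0.068 g dead-band;
5. quantize: floor(value / 0.0164 g);
6. accumulate 10 samples (1 s) per bin, then sum bins into 60-s epochs.

The epoch grid is anchored to whole minutes of the local clock so that daily
summaries are midnight-aligned; a partial trailing epoch is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter, lfilter_zi

from .errors import ConfigError, EmptySeriesError
from .io_formats import RawTriaxialRecording

# Versioned constant table of the count-emulation chain (v1).
# Band-pass replication of the legacy device's movement filter: order-3
# Butterworth over the published 0.29-1.66 Hz band at 30 Hz, peak-normalised
# so the in-band gain matches the published 0.965 peak.  Frozen as literals so
# the chain is reproducible independent of the filter-design library.
BAND_PASS_B = np.array(
    [
        0.00218126847591198, 0.0, -0.00654380542773594, 0.0,
        0.00654380542773594, 0.0, -0.00218126847591198,
    ]
)
BAND_PASS_A = np.array(
    [
        1.0, -5.370387623242325, 12.084006271576468, -14.587935246593048,
        9.967824152991971, -3.6557128361120075, 0.5622124511936685,
    ]
)
FILTER_GAIN = 1.0  # normalisation is folded into BAND_PASS_B


@dataclass
class CountParams:
    """Parameters of the count-emulation chain.

    Defaults are the published emulation constants and should not normally be
    changed; they are exposed so the chain is testable stage by stage.

    Attributes
    ----------
    intermediate_rate : float
        Rate the raw signal is resampled to before filtering (Hz).
    accumulator_rate : float
        Rate after decimation, at which the ADC model operates (Hz).
    dead_band : float
        Rectified values at or below this (g) produce no counts.
    saturation : float
        Filter output is clipped to ± this peak (g).
    adc_resolution : float
        Quantization step (g per count unit).
    accumulation_s : float
        Length of the pre-epoch accumulation bin (s).
    """

    intermediate_rate: float = 30.0
    accumulator_rate: float = 10.0
    band_pass_b: np.ndarray = field(default_factory=lambda: BAND_PASS_B.copy())
    band_pass_a: np.ndarray = field(default_factory=lambda: BAND_PASS_A.copy())
    filter_gain: float = FILTER_GAIN
    dead_band: float = 0.068
    saturation: float = 2.13
    adc_resolution: float = 0.0164
    accumulation_s: float = 1.0

    def __post_init__(self) -> None:
        if self.dead_band >= self.saturation:
            raise ConfigError(
                f"dead_band ({self.dead_band}) must be below saturation ({self.saturation})"
            )
        if self.intermediate_rate <= 0 or self.accumulator_rate <= 0:
            raise ConfigError("rates must be positive")
        ratio = self.intermediate_rate / self.accumulator_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("intermediate_rate must be an integer multiple of accumulator_rate")
        if self.adc_resolution <= 0:
            raise ConfigError("adc_resolution must be positive")

    @property
    def quantization_levels(self) -> int:
        """Number of ADC steps between zero and saturation."""
        return int(self.saturation / self.adc_resolution)


@dataclass
class CountEpochSeries:
    """Per-epoch, per-axis activity counts on a fixed minute-anchored grid."""

    epoch_start: pd.DatetimeIndex
    counts: np.ndarray  # (n, 3) int64
    vm: np.ndarray | None = None
    epoch_length: int = 60

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ConfigError("counts must have shape (n, 3)")
        if (self.counts < 0).any():
            raise ConfigError("counts must be non-negative")
        if len(self.epoch_start) != len(self.counts):
            raise ConfigError("epoch grid and counts length mismatch")
        if len(self.epoch_start) > 1:
            steps = np.diff(self.epoch_start.asi8)
            step_ns = self.epoch_length * 1_000_000_000
            # gaps (missing epochs) are allowed; off-grid or repeated starts are not
            if (steps <= 0).any() or (steps % step_ns != 0).any():
                raise ConfigError("epoch starts must be increasing on the epoch_length grid")
        if self.vm is not None:
            self.vm = np.asarray(self.vm, dtype=np.float64)
            if len(self.vm) != len(self.counts):
                raise ConfigError("vm length mismatch")

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "epoch_start": self.epoch_start,
                "counts_x": self.counts[:, 0],
                "counts_y": self.counts[:, 1],
                "counts_z": self.counts[:, 2],
            }
        )
        if self.vm is not None:
            df["vm"] = self.vm
        return df


def emulate_counts(
    raw: RawTriaxialRecording,
    params: CountParams | None = None,
    epoch_length: int = 60,
) -> CountEpochSeries:
    """Run the count-emulation chain and aggregate into epochs.

    The output grid starts at the first whole-minute boundary at or after
    ``raw.start_time``; any partial trailing epoch is discarded.  ``vm`` is
    left unpopulated — apply :func:`vector_magnitude`.
    """
    params = params or CountParams()
    if raw.rate < params.intermediate_rate:
        raise ConfigError(
            f"input rate {raw.rate} Hz below intermediate rate {params.intermediate_rate} Hz"
        )
    if raw.duration_s < epoch_length:
        raise EmptySeriesError(
            f"recording of {raw.duration_s:.1f} s is shorter than one {epoch_length}-s epoch"
        )

    ir = params.intermediate_rate
    decim = int(round(ir / params.accumulator_rate))
    n = raw.n_samples
    # linear interpolation onto the intermediate-rate grid
    t_src = np.arange(n, dtype=np.float64) / raw.rate
    n_ir = int(np.floor(t_src[-1] * ir)) + 1
    t_dst = np.arange(n_ir, dtype=np.float64) / ir

    per_axis_seconds = []
    acc_len = int(round(params.accumulator_rate * params.accumulation_s))
    for axis in range(3):
        x = np.interp(t_dst, t_src, raw.samples[:, axis].astype(np.float64))
        # steady-state initial condition for x[0] suppresses the start-up
        # transient a zero-state filter would turn into phantom counts
        b = params.filter_gain * params.band_pass_b
        zi = lfilter_zi(b, params.band_pass_a) * x[0]
        y, _ = lfilter(b, params.band_pass_a, x, zi=zi)
        y = y[::decim]
        y = np.clip(y, -params.saturation, params.saturation)
        y = np.abs(y)
        y[y < params.dead_band] = 0.0
        q = np.floor(y / params.adc_resolution)
        n_bins = len(q) // acc_len
        bins = q[: n_bins * acc_len].reshape(n_bins, acc_len).sum(axis=1)
        per_axis_seconds.append(bins)

    n_sec = min(len(b) for b in per_axis_seconds)
    per_sec = np.stack([b[:n_sec] for b in per_axis_seconds], axis=1)

    # anchor to the first whole minute of the local clock
    first_epoch = raw.start_time.ceil(f"{epoch_length}s")
    offset_s = (first_epoch - raw.start_time).total_seconds()
    offset_bins = int(round(offset_s / params.accumulation_s))
    bins_per_epoch = int(round(epoch_length / params.accumulation_s))
    n_epochs = (n_sec - offset_bins) // bins_per_epoch
    if n_epochs <= 0:
        raise EmptySeriesError("recording covers no whole epoch on the minute grid")
    used = per_sec[offset_bins : offset_bins + n_epochs * bins_per_epoch]
    epochs = used.reshape(n_epochs, bins_per_epoch, 3).sum(axis=1).astype(np.int64)
    grid = pd.date_range(first_epoch, periods=n_epochs, freq=f"{epoch_length}s")
    return CountEpochSeries(epoch_start=grid, counts=epochs, epoch_length=epoch_length)


def vector_magnitude(series: CountEpochSeries) -> CountEpochSeries:
    """Populate the per-epoch resultant vector magnitude (unrounded Euclidean norm)."""
    vm = np.sqrt((series.counts.astype(np.float64) ** 2).sum(axis=1))
    return CountEpochSeries(
        epoch_start=series.epoch_start,
        counts=series.counts,
        vm=vm,
        epoch_length=series.epoch_length,
    )
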