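"""Readers, writers and domain containers for every external representation.

Two sensor streams enter the pipeline:

* a wrist-mounted tri-axial accelerometer on the prosthesis (raw signal, CSV or
  the resampled 3-channel WAV export dialect some monitor toolchains produce);
* a thigh-worn activity monitor whose vendor software exports one row per 60-s
  epoch with the number of seconds spent in each activity class plus a step
  count.

All timestamps are timezone-naive local clock time: every downstream summary is
anchored to local midnight, so local wall time is the analysis clock.
Readers never repair data — monotonicity or bookkeeping violations raise
:class:`~limbwear.errors.IntegrityError` rather than being silently fixed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import ConfigError, FormatError, IntegrityError

#: Activity classes reported by the thigh monitor's epoch export, canonical order.
ACTIVITY_CLASSES = (
    "sedentary",
    "upright",
    "stepping",
    "cycling",
    "primary_lying",
    "secondary_lying",
    "seated_transport",
    "non_wear",
)

#: Seconds per behaviour epoch.
EPOCH_S = 60

#: Tolerance on the per-row sum of class seconds (exports round per-class values).
EPOCH_SUM_TOL_S = 0.5


def _as_naive_timestamp(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    if ts.tz is not None:
        raise ConfigError("timestamps must be timezone-naive local clock time")
    return ts


@dataclass
class RawTriaxialRecording:
    """A regularly sampled tri-axial acceleration signal in units of g.

    Parameters
    ----------
    start_time : timestamp-like
        Local wall time of the first sample (second resolution or better).
    rate : float
        Sampling rate in Hz.
    samples : ndarray, shape (n, 3)
        Acceleration in g, columns x/y/z.
    device_range : float
        Full-scale range of the sensor, ± g.
    """

    start_time: pd.Timestamp
    rate: float
    samples: np.ndarray
    device_range: float = 16.0
    participant_id: str = ""
    body_site: str = "prosthetic_wrist"

    def __post_init__(self) -> None:
        self.start_time = _as_naive_timestamp(self.start_time)
        if self.rate <= 0:
            raise ConfigError(f"rate must be positive, got {self.rate}")
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(
                f"samples must have shape (n, 3), got {self.samples.shape}"
            )
        if self.device_range <= 0:
            raise ConfigError("device_range must be positive")
        peak = float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0
        if peak > self.device_range * (1 + 1e-6):
            raise IntegrityError(
                f"|sample| = {peak:.3f} g exceeds device range ±{self.device_range} g"
            )
        if self.body_site not in {"prosthetic_wrist", "socket_distal", "thigh"}:
            raise ConfigError(f"unknown body_site {self.body_site!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        """Recording duration: sample count / rate."""
        return self.n_samples / self.rate

    def times(self) -> pd.DatetimeIndex:
        """Implied per-sample timestamps (strictly increasing by construction)."""
        step = pd.to_timedelta(np.arange(self.n_samples) / self.rate, unit="s")
        return pd.DatetimeIndex(self.start_time + step)


@dataclass
class BehaviourEpochTable:
    """Per-minute activity breakdown from the thigh monitor.

    Wraps a DataFrame indexed by ``epoch_start`` (strictly increasing, on the
    60-s grid) with one integer/float column of seconds per activity class in
    :data:`ACTIVITY_CLASSES` plus a ``steps`` column.  Gaps in the grid are
    legitimate and represent missing epochs; they are never zero-filled.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in (*ACTIVITY_CLASSES, "steps") if c not in df.columns]
        if missing:
            raise FormatError(f"behaviour table missing columns: {missing}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise FormatError("behaviour table must be indexed by epoch_start")
        if df.index.tz is not None:
            raise ConfigError("epoch_start must be timezone-naive")
        if len(df):
            if not df.index.is_monotonic_increasing or df.index.has_duplicates:
                raise IntegrityError("epoch_start values must be strictly increasing")
            if (df.index != df.index.floor("min")).any():
                raise IntegrityError("epoch_start values must lie on the 60-s grid")
            sums = df[list(ACTIVITY_CLASSES)].sum(axis=1).to_numpy(dtype=float)
            bad = np.flatnonzero(np.abs(sums - EPOCH_S) > EPOCH_SUM_TOL_S)
            if bad.size:
                raise IntegrityError(
                    f"class seconds sum to {sums[bad[0]]:g} (not 60 ± {EPOCH_SUM_TOL_S}) "
                    f"at row {bad[0]} ({df.index[bad[0]]})"
                )
            steps = df["steps"].to_numpy(dtype=float)
            if (steps < 0).any():
                raise IntegrityError("steps must be non-negative")
            stepping = df["stepping"].to_numpy(dtype=float)
            bad = np.flatnonzero((steps > 0) & (stepping <= 0))
            if bad.size:
                raise IntegrityError(
                    f"steps > 0 with zero stepping seconds at row {bad[0]}"
                )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def epoch_start(self) -> pd.DatetimeIndex:
        return self.data.index

    def missing_epochs(self) -> pd.DatetimeIndex:
        """Grid epochs between first and last row that carry no data."""
        if len(self.data) < 2:
            return pd.DatetimeIndex([])
        full = pd.date_range(self.data.index[0], self.data.index[-1], freq="60s")
        return full.difference(self.data.index)


@dataclass
class Dialect:
    """Column/format mapping for one source file layout.

    ``column_map`` maps source column names to canonical field names
    (``time, x, y, z`` for raw wrist CSVs; the activity classes and ``steps``
    for behaviour tables; ``epoch_start`` for the epoch timestamp).
    ``wav_scale`` is g per unit full-scale amplitude for WAV wrist exports and
    ``wav_channel_order`` assigns the three WAV channels to axes.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    time_format: str | None = None
    wav_scale: float = 1.0
    wav_channel_order: tuple[str, str, str] = ("x", "y", "z")

    def __post_init__(self) -> None:
        if self.wav_scale <= 0:
            raise ConfigError("wav_scale must be positive")
        if sorted(self.wav_channel_order) != ["x", "y", "z"]:
            raise ConfigError("wav_channel_order must be a permutation of x, y, z")

    def rename(self, df: pd.DataFrame, mandatory: Iterable[str]) -> pd.DataFrame:
        out = df.rename(columns=self.column_map) if self.column_map else df
        missing = [c for c in mandatory if c not in out.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {missing}")
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "wav_channel_order" in raw:
            raw["wav_channel_order"] = tuple(raw["wav_channel_order"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers


def read_raw_wrist(
    path: str | Path,
    dialect: Dialect | None = None,
    *,
    start_time=None,
    participant_id: str = "",
    device_range: float = 16.0,
) -> RawTriaxialRecording:
    """Read a raw wrist recording from CSV (time,x,y,z) or 3-channel WAV.

    WAV files carry no timestamps; ``start_time`` must then be supplied.
    Integer PCM samples are normalised to full scale before applying
    ``dialect.wav_scale`` (g per unit amplitude); float WAV samples are taken
    as already normalised.
    """
    path = Path(path)
    dialect = dialect or Dialect()
    if path.suffix.lower() == ".wav":
        return _read_wrist_wav(path, dialect, start_time, participant_id, device_range)
    return _read_wrist_csv(path, dialect, participant_id, device_range)


def _read_wrist_csv(path, dialect, participant_id, device_range):
    df = pd.read_csv(path)
    df = dialect.rename(df, mandatory=("time", "x", "y", "z"))
    if dialect.time_format:
        t = pd.to_datetime(df["time"], format=dialect.time_format)
    else:
        t = pd.to_datetime(df["time"])
    dt = t.diff().dt.total_seconds().to_numpy()[1:]
    if len(dt) and (dt <= 0).any():
        i = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise IntegrityError(f"timestamps not strictly increasing at row {i}")
    if len(dt):
        step = float(np.median(dt))
        if np.abs(dt - step).max() > 0.25 * step:
            raise IntegrityError("sampling grid is irregular beyond tolerance")
        rate = 1.0 / step
    else:
        rate = 1.0
    samples = df[["x", "y", "z"]].to_numpy(dtype=np.float32)
    return RawTriaxialRecording(
        start_time=t.iloc[0],
        rate=round(rate, 6),
        samples=samples,
        device_range=device_range,
        participant_id=participant_id,
    )


def _read_wrist_wav(path, dialect, start_time, participant_id, device_range):
    if start_time is None:
        raise ConfigError("WAV input carries no timestamps; start_time is required")
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 3:
        n = 1 if data.ndim == 1 else data.shape[1]
        raise FormatError(f"expected 3 WAV channels (x,y,z), got {n}")
    if np.issubdtype(data.dtype, np.integer):
        full_scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / full_scale
    samples = np.empty((data.shape[0], 3), dtype=np.float32)
    for ch, axis in enumerate(dialect.wav_channel_order):
        samples[:, "xyz".index(axis)] = data[:, ch] * dialect.wav_scale
    return RawTriaxialRecording(
        start_time=start_time,
        rate=float(rate),
        samples=samples,
        device_range=device_range,
        participant_id=participant_id,
    )


def read_behaviour_epochs(path: str | Path, dialect: Dialect | None = None) -> BehaviourEpochTable:
    """Read a thigh-monitor epoch export (one row per 60-s epoch).

    Grid gaps are preserved as missing epochs; rows whose class seconds do not
    sum to 60 (± 0.5 s) raise :class:`IntegrityError` naming the row.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path)
    df = dialect.rename(df, mandatory=("epoch_start", *ACTIVITY_CLASSES, "steps"))
    if dialect.time_format:
        idx = pd.to_datetime(df["epoch_start"], format=dialect.time_format)
    else:
        idx = pd.to_datetime(df["epoch_start"])
    out = df[[*ACTIVITY_CLASSES, "steps"]].copy()
    out.index = pd.DatetimeIndex(idx, name="epoch_start")
    return BehaviourEpochTable(out)


# ---------------------------------------------------------------------------
# writers


def write_raw_wrist(rec: RawTriaxialRecording, path: str | Path) -> None:
    """Write a recording as CSV (time,x,y,z) with millisecond timestamps."""
    df = pd.DataFrame(rec.samples.astype(np.float64), columns=["x", "y", "z"])
    df.insert(0, "time", rec.times().strftime("%Y-%m-%dT%H:%M:%S.%f"))
    df.to_csv(path, index=False, float_format="%.6f")


def write_behaviour_epochs(table: BehaviourEpochTable, path: str | Path) -> None:
    df = table.data.reset_index()
    df["epoch_start"] = df["epoch_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def export_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    config: Mapping | None = None,
    input_paths: Iterable[str | Path] = (),
    seed: int | None = None,
) -> list[Path]:
    """Deterministically export result tables plus a run manifest.

    Each table is written as ``<name>.csv`` with its column order preserved,
    ISO-8601 timestamps and '.' decimal separator.  ``manifest.json`` records a
    hash of the configuration, checksums of the input files and the seed, and
    contains nothing volatile (no wall-clock time), so identical runs produce
    byte-identical file sets.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: list[Path] = []
    for name in sorted(tables):
        df = tables[name].copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
        dest = out_dir / f"{name}.csv"
        df.to_csv(dest, index=False)
        written.append(dest)

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": json.loads(cfg_json),
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in input_paths},
        "outputs": [p.name for p in written],
    }
    dest = out_dir / "manifest.json"
    with open(dest, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(dest)
    return written
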