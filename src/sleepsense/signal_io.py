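"""Readers and writers for Empatica-E4-style channel exports, diaries and feature tables.

All internal times are UTC seconds (float).  A calendar "night" is keyed to the
date of the morning diary response.  Intervals are half-open ``[start, end)``:
a sample at time ``t`` belongs to a window iff ``start <= t < end``.

The E4 export dialect: line 1 holds the UNIX start time of the recording,
line 2 the sampling rate in Hz, and every following line one sample tick.
ACC rows carry three comma-separated raw integers in units of 1/64 g.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ChannelRecording",
    "DiaryEntry",
    "RecordingSession",
    "CHANNEL_RATES",
    "ACC_SCALE",
    "read_e4_channel",
    "write_e4_channel",
    "read_ibi_file",
    "write_ibi_file",
    "read_diary",
    "write_diary",
    "read_feature_table",
    "write_feature_table",
    "load_session_dir",
    "write_session_dir",
]


class FormatError(ValueError):
    """A file does not parse as the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


#: Nominal sampling rates of the four E4 channels (Hz).
CHANNEL_RATES = {"BVP": 64.0, "EDA": 4.0, "ACC": 32.0, "TEMP": 4.0}

#: Raw accelerometer integers are in units of 1/64 g (E4 export convention).
ACC_SCALE = 1.0 / 64.0


@dataclasses.dataclass
class ChannelRecording:
    """One uniformly sampled sensor channel.

    Parameters
    ----------
    channel : {"BVP", "EDA", "ACC", "TEMP"}
    start_time : float
        Absolute UTC timestamp of the first sample, seconds.
    fs : float
        Sampling rate, Hz.
    samples : ndarray
        Shape ``(n,)``; for ACC shape ``(n, 3)`` in g.  EDA is in
        microsiemens, TEMP in deg C, BVP in arbitrary units.
    """

    channel: str
    start_time: float
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.channel not in CHANNEL_RATES:
            raise ValidationError(f"unknown channel {self.channel!r}")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.shape[0] < 1:
            raise ValidationError(f"{self.channel} recording has no samples")
        if self.channel == "ACC":
            if self.samples.ndim != 2 or self.samples.shape[1] != 3:
                raise ValidationError("ACC samples must have shape (n, 3)")
        elif self.samples.ndim != 1:
            raise ValidationError(f"{self.channel} samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"{self.channel} recording contains non-finite samples")

    def validate_strict(self) -> None:
        """Check the channel <-> rate pairing the E4 guarantees."""
        expected = CHANNEL_RATES[self.channel]
        if abs(self.fs - expected) > 1e-9:
            raise ValidationError(
                f"{self.channel} expects fs={expected} Hz, got {self.fs}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        """Covered interval length in seconds (half-open)."""
        return self.n_samples / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Implied timestamp of sample ``i``: ``start_time + i / fs``."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def slice_interval(self, start: float, end: float) -> np.ndarray:
        """Samples whose timestamps fall in the half-open ``[start, end)``."""
        i0 = int(np.ceil((start - self.start_time) * self.fs - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.fs - 1e-9))
        i0 = max(i0, 0)
        i1 = min(max(i1, i0), self.n_samples)
        return self.samples[i0:i1]


def phase_masks(times: np.ndarray, onset: float, wake: float,
                awake_window: Optional[tuple] = None):
    """Awake/asleep boolean masks over timestamps.

    Asleep is the half-open ``[onset, wake)``.  Awake is everything else,
    optionally restricted to ``awake_window`` (e.g. the 24 hours preceding
    wake); timestamps outside both are excluded from either phase.
    """
    times = np.asarray(times, dtype=float)
    asleep = (times >= onset) & (times < wake)
    awake = ~asleep
    if awake_window is not None:
        lo, hi = awake_window
        awake &= (times >= lo) & (times < hi)
    return awake, asleep


@dataclasses.dataclass
class DiaryEntry:
    """One morning's sleep-diary response."""

    participant_id: str
    night_date: _dt.date
    reported_bedtime: float
    reported_waketime: float
    sleep_quality: int

    def __post_init__(self) -> None:
        if not self.reported_bedtime < self.reported_waketime:
            raise ValidationError(
                f"{self.participant_id}/{self.night_date}: bedtime must precede waketime"
            )
        if int(self.sleep_quality) != self.sleep_quality or not 1 <= self.sleep_quality <= 5:
            raise ValidationError(
                f"sleep quality must be an integer in 1..5, got {self.sleep_quality}"
            )
        self.sleep_quality = int(self.sleep_quality)


@dataclasses.dataclass
class RecordingSession:
    """All channels, optional device IBIs and the diary entry of one night."""

    participant_id: str
    night_date: _dt.date
    channels: Dict[str, ChannelRecording]
    device_ibis: Optional[object] = None  # cardiac.IBISeries
    diary: Optional[DiaryEntry] = None

    def validate_strict(self, margin_h: float = 4.0) -> None:
        """Require every channel to cover [bedtime - margin, waketime + margin]."""
        if self.diary is None:
            raise ValidationError("strict validation requires a diary entry")
        lo = self.diary.reported_bedtime - margin_h * 3600.0
        hi = self.diary.reported_waketime + margin_h * 3600.0
        for rec in self.channels.values():
            rec.validate_strict()
            if rec.start_time > lo + 1e-6 or rec.end_time < hi - 1e-6:
                raise ValidationError(
                    f"{rec.channel} does not cover the protocol window "
                    f"[{lo}, {hi}] (covers [{rec.start_time}, {rec.end_time}])"
                )


# ---------------------------------------------------------------------------
# E4 channel CSVs
# ---------------------------------------------------------------------------

def _parse_header_number(line: str, lineno: int, path: Path) -> float:
    field = line.split(",")[0].strip()
    try:
        return float(field)
    except ValueError as exc:
        raise FormatError(f"{path}: line {lineno} is not numeric: {line!r}") from exc


def read_e4_channel(path, channel: str) -> ChannelRecording:
    """Read one E4-style channel CSV.

    Line 1 is the UNIX start time, line 2 the sampling rate; every further
    line is one sample tick.  ACC rows have three comma-separated raw
    integers which are scaled by 1/64 to g.
    """
    path = Path(path)
    if channel not in CHANNEL_RATES:
        raise ValidationError(f"unknown channel {channel!r}")
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected start-time and rate header lines")
    start_time = _parse_header_number(lines[0], 1, path)
    fs = _parse_header_number(lines[1], 2, path)
    if fs <= 0:
        raise FormatError(f"{path}: line 2 must be a positive sampling rate, got {fs}")
    body = lines[2:]
    if not body:
        raise ValidationError(f"{path}: no samples after header")
    try:
        if channel == "ACC":
            rows = [[float(x) for x in ln.split(",")] for ln in body]
            arr = np.asarray(rows, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"{path}: ACC rows must have 3 columns")
            samples = arr * ACC_SCALE
        else:
            samples = np.asarray([float(ln.split(",")[0]) for ln in body], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed sample row: {exc}") from exc
    if not np.all(np.isfinite(samples)):
        raise ValidationError(f"{path}: NaN or infinite sample values")
    return ChannelRecording(channel=channel, start_time=start_time, fs=fs, samples=samples)


def write_e4_channel(path, recording: ChannelRecording) -> None:
    """Inverse of :func:`read_e4_channel` (6-decimal sample formatting)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{recording.start_time:.6f}\n")
        fh.write(f"{recording.fs:.6f}\n")
        if recording.channel == "ACC":
            raw = np.rint(recording.samples / ACC_SCALE).astype(int)
            for row in raw:
                fh.write(f"{row[0]},{row[1]},{row[2]}\n")
        else:
            for v in recording.samples:
                fh.write(f"{v:.6f}\n")


# ---------------------------------------------------------------------------
# Device IBI files
# ---------------------------------------------------------------------------

def read_ibi_file(path):
    """Read a device IBI export.

    The header row carries the session start time as ``<start>,IBI``; every
    further row is ``<offset seconds from start>,<ibi seconds>``.  IBIs are
    converted to milliseconds.  A beat is *contiguous* when the offset gap to
    the previous beat matches its stated IBI; larger gaps mark segments the
    device dropped (e.g. motion artifacts).  Out-of-range IBIs (<= 0 or
    > 3000 ms) are retained but flagged invalid.
    """
    from .cardiac import IBISeries  # deferred: cardiac imports this module

    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty IBI file")
    start_time = _parse_header_number(lines[0], 1, path)
    offsets: List[float] = []
    ibis_ms: List[float] = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split(",")
        if len(parts) != 2:
            raise FormatError(f"{path}: line {i} must be 'offset,ibi': {ln!r}")
        try:
            off, ibi_s = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i} is not numeric: {ln!r}") from exc
        offsets.append(off)
        ibis_ms.append(ibi_s * 1000.0)
    offsets_a = np.asarray(offsets)
    ibis_a = np.asarray(ibis_ms)
    if np.any(np.diff(offsets_a) <= 0):
        raise ValidationError(f"{path}: beat offsets must be strictly increasing")
    valid = (ibis_a > 0) & (ibis_a <= 3000.0)
    contiguous = np.zeros(len(offsets_a), dtype=bool)
    if len(offsets_a) > 1:
        gaps = np.diff(offsets_a) * 1000.0
        contiguous[1:] = np.abs(gaps - ibis_a[1:]) <= 10.0  # ms; file rounding slack
    return IBISeries(
        beat_times=start_time + offsets_a,
        ibis=ibis_a,
        valid=valid,
        contiguous=contiguous,
        source="device",
    )


def write_ibi_file(path, ibis, start_time: Optional[float] = None) -> None:
    """Inverse of :func:`read_ibi_file`."""
    path = Path(path)
    if start_time is None:
        start_time = float(ibis.beat_times[0]) - float(ibis.ibis[0]) / 1000.0 if len(ibis) else 0.0
    with open(path, "w") as fh:
        fh.write(f"{start_time:.6f},IBI\n")
        for t, ibi in zip(ibis.beat_times, ibis.ibis):
            fh.write(f"{t - start_time:.6f},{ibi / 1000.0:.6f}\n")


# ---------------------------------------------------------------------------
# Diaries
# ---------------------------------------------------------------------------

_DIARY_COLUMNS = [
    "participant_id",
    "night_date",
    "reported_bedtime",
    "reported_waketime",
    "sleep_quality",
]


def _iso_to_seconds(value: str) -> float:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return float(ts.timestamp())


def _seconds_to_iso(seconds: float) -> str:
    return pd.Timestamp(seconds, unit="s", tz="UTC").isoformat()


def read_diary(path) -> List[DiaryEntry]:
    """Read a diary CSV with ISO-8601 timestamps into validated entries."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(_DIARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: diary is missing columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            DiaryEntry(
                participant_id=str(row["participant_id"]),
                night_date=pd.Timestamp(row["night_date"]).date(),
                reported_bedtime=_iso_to_seconds(row["reported_bedtime"]),
                reported_waketime=_iso_to_seconds(row["reported_waketime"]),
                sleep_quality=int(row["sleep_quality"]),
            )
        )
    return entries


def write_diary(path, entries: List[DiaryEntry]) -> None:
    df = pd.DataFrame(
        {
            "participant_id": [e.participant_id for e in entries],
            "night_date": [e.night_date.isoformat() for e in entries],
            "reported_bedtime": [_seconds_to_iso(e.reported_bedtime) for e in entries],
            "reported_waketime": [_seconds_to_iso(e.reported_waketime) for e in entries],
            "sleep_quality": [e.sleep_quality for e in entries],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(path, table: pd.DataFrame) -> None:
    """Write per-night observations (identity, response, 52 features) to CSV."""
    table.to_csv(path, index=False, float_format="%.9f")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    from .dataset import FEATURE_NAMES  # deferred: avoids an import cycle

    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "night_date", "response"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: feature table is missing columns {sorted(missing)}")
    unknown = set(df.columns) - required - set(FEATURE_NAMES)
    if unknown:
        raise FormatError(f"{path}: unknown feature columns {sorted(unknown)}")
    bad = ~df["response"].isin([1, 2, 3, 4, 5])
    if bad.any():
        raise ValidationError(f"{path}: responses outside 1..5 in {int(bad.sum())} rows")
    df["night_date"] = pd.to_datetime(df["night_date"]).dt.date
    return df


# ---------------------------------------------------------------------------
# Session directories
# ---------------------------------------------------------------------------

def load_session_dir(session_dir, diary_entry: Optional[DiaryEntry] = None) -> RecordingSession:
    """Load BVP/EDA/ACC/TEMP.csv (and IBI.csv if present) from one directory.

    The directory is expected to be ``<participant_id>/<night_date>/`` shaped;
    identity is taken from the path when no diary entry is supplied.
    """
    session_dir = Path(session_dir)
    channels = {}
    for channel in CHANNEL_RATES:
        f = session_dir / f"{channel}.csv"
        if f.exists():
            channels[channel] = read_e4_channel(f, channel)
    if not channels:
        raise FormatError(f"{session_dir}: no channel CSVs found")
    ibi_path = session_dir / "IBI.csv"
    device_ibis = read_ibi_file(ibi_path) if ibi_path.exists() else None
    if diary_entry is not None:
        pid, date = diary_entry.participant_id, diary_entry.night_date
    else:
        pid = session_dir.parent.name
        date = _dt.date.fromisoformat(session_dir.name)
    return RecordingSession(
        participant_id=pid,
        night_date=date,
        channels=channels,
        device_ibis=device_ibis,
        diary=diary_entry,
    )


def write_session_dir(session_dir, session: RecordingSession) -> None:
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    for channel, rec in session.channels.items():
        write_e4_channel(session_dir / f"{channel}.csv", rec)
    if session.device_ibis is not None and len(session.device_ibis):
        start = min(r.start_time for r in session.channels.values())
        write_ibi_file(session_dir / "IBI.csv", session.device_ibis, start_time=start)
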