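"""Readers, writers and parsing for the five per-session file streams.

Each session is a directory of plain-text files on two unaligned device
clocks: a ~10 Hz phone sensor log (elapsed seconds), an RR-interval stream
from the ECG chest strap (milliseconds, no timestamps), a 1 Hz wrist record
stream timestamped as local-time strings with no date component, a
lap-event timeline (ordered start seconds on the watch clock) and a session
log. The dialects are comma-separated UTF-8 with one header row; the wrist
record's 25 Hz accelerometer burst is packed as a bracketed JSON array in a
single quoted field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

COMFORTABLE = "comfortable"
UNCOMFORTABLE = "uncomfortable"

PHONE_COLUMNS = [
    "t_elapsed",
    "ax", "ay", "az",
    "gyro_x", "gyro_y", "gyro_z",
    "grav_x", "grav_y", "grav_z",
    "mag_x", "mag_y", "mag_z",
    "sound", "lux",
]

RECORD_COLUMNS = [
    "local_time", "hr", "wrist_temp", "packed_accel",
    "pressure", "altitude", "gps_speed", "heading",
]

#: samples per packed wrist-accelerometer row (25 Hz burst per 1 s row)
PACKED_ACCEL_LEN = 25

PHONE_FILE = "phone.csv"
RR_FILE = "rr.csv"
RECORDS_FILE = "records.csv"
LAPS_FILE = "laps.csv"
META_FILE = "session.json"


class StreamError(Exception):
    """Base class for stream ingestion failures."""


class MissingStreamError(StreamError):
    """A required per-session file is absent; the session is excluded."""

    def __init__(self, stream: str, path: Path):
        self.stream = stream
        self.path = Path(path)
        super().__init__(f"required stream '{stream}' missing: {path}")


class MalformedRowError(StreamError):
    """A row failed to parse; carries the 1-based data line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(message + where)


class StreamOrderError(StreamError):
    """Timestamps are not in the required monotone order."""


@dataclass
class PhoneStream:
    """Phone sensor log at a nominal 10 Hz on the phone's elapsed clock.

    Accelerometer fields are linear acceleration (gravity removed); the
    gravity vector is carried separately. Sound is the microphone level in
    dB as recorded (a consistent relative measure, not calibrated SPL).
    """

    data: pd.DataFrame  # columns PHONE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in PHONE_COLUMNS if c not in self.data.columns]
        if missing:
            raise MalformedRowError(f"phone stream missing columns {missing}")
        t = self.data["t_elapsed"].to_numpy(float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise StreamOrderError("phone t_elapsed must be strictly increasing")

    @property
    def t_elapsed(self) -> np.ndarray:
        return self.data["t_elapsed"].to_numpy(float)

    def accel_magnitude(self) -> np.ndarray:
        a = self.data[["ax", "ay", "az"]].to_numpy(float)
        return np.linalg.norm(a, axis=1)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RRStream:
    """RR intervals in ms, ordered as received from the chest strap."""

    rr: np.ndarray

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise MalformedRowError("rr stream must be one-dimensional")
        if len(self.rr) and np.any(self.rr <= 0):
            raise MalformedRowError("rr intervals must be positive")

    def __len__(self) -> int:
        return len(self.rr)


@dataclass
class WristRecordStream:
    """1 Hz watch record stream: local-time strings, HR, wrist temperature,
    packed 25-sample accelerometer bursts, pressure, altitude, GPS speed
    (nullable — missingness is meaningful and never zero-filled) and heading."""

    data: pd.DataFrame  # columns RECORD_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise MalformedRowError(f"record stream missing columns {missing}")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class LapTimeline:
    """Ordered lap-start seconds on the watch clock with manual corrections.

    Comfort state is parity-encoded: even lap indices are comfortable, odd
    are uncomfortable, and the session starts comfortable. Missed presses
    are corrected by overriding a lap index's state or inserting extra
    boundaries; corrections are applied before any labelling.
    """

    lap_starts: np.ndarray
    overrides: dict[int, str] = field(default_factory=dict)
    inserted_boundaries: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lap_starts = np.asarray(self.lap_starts, dtype=float)
        if len(self.lap_starts) == 0:
            raise MalformedRowError("lap timeline must contain at least one start")
        if len(self.lap_starts) > 1 and not np.all(np.diff(self.lap_starts) > 0):
            raise StreamOrderError("lap starts must be strictly increasing")
        for state in self.overrides.values():
            if state not in (COMFORTABLE, UNCOMFORTABLE):
                raise MalformedRowError(f"unknown comfort state {state!r}")

    def effective_boundaries(self) -> tuple[np.ndarray, list[str]]:
        """Boundary times and per-lap states after corrections.

        Inserted boundaries are merged into the lap list before the parity
        rule is applied; index overrides then replace the state of single
        laps without flipping the parity of later laps.
        """
        starts = sorted(set(self.lap_starts.tolist()) | set(self.inserted_boundaries))
        states = [COMFORTABLE if i % 2 == 0 else UNCOMFORTABLE for i in range(len(starts))]
        for idx, state in self.overrides.items():
            if not 0 <= idx < len(starts):
                raise IndexError(f"lap override index {idx} out of range")
            states[idx] = state
        return np.asarray(starts, dtype=float), states

    def __len__(self) -> int:
        return len(self.lap_starts)


@dataclass
class SessionMeta:
    """Session log entry: date, start time, location and indoor flag."""

    date: str  # ISO YYYY-MM-DD
    start_time: str  # HH:MM:SS local
    location_name: str = ""
    lat: float = 0.0
    lon: float = 0.0
    indoor: bool = True
    notes: str = ""


@dataclass
class SessionBundle:
    """All raw streams and metadata for one session, on two unaligned clocks."""

    session_id: str
    phone: PhoneStream
    rr: RRStream
    records: WristRecordStream
    laps: LapTimeline
    meta: SessionMeta


# ---------------------------------------------------------------------------
# readers / writers


def _require(path: Path, stream: str) -> Path:
    path = Path(path)
    if not path.exists():
        raise MissingStreamError(stream, path)
    return path


def read_phone_stream(path) -> PhoneStream:
    path = _require(path, "phone")
    df = pd.read_csv(path)
    return PhoneStream(df[PHONE_COLUMNS].astype(float))


def write_phone_stream(stream: PhoneStream, path) -> None:
    stream.data.to_csv(path, index=False, float_format="%.6g")


def read_rr(path) -> RRStream:
    path = _require(path, "rr")
    df = pd.read_csv(path)
    if "rr" not in df.columns:
        raise MalformedRowError("rr stream must have an 'rr' column")
    return RRStream(df["rr"].to_numpy(float))


def write_rr(stream: RRStream, path) -> None:
    pd.DataFrame({"rr": stream.rr}).to_csv(path, index=False, float_format="%.6g")


def read_records(path) -> WristRecordStream:
    path = _require(path, "records")
    df = pd.read_csv(path, dtype={"local_time": str, "packed_accel": str})
    stream = WristRecordStream(df[RECORD_COLUMNS])
    # validate every packed field eagerly so bad rows carry line numbers
    for i, row in enumerate(df.itertuples(index=False)):
        unpack_packed_accel_field(row.packed_accel, line=i + 1)
    return stream


def write_records(stream: WristRecordStream, path) -> None:
    stream.data.to_csv(path, index=False, float_format="%.6g")


def read_laps(path) -> LapTimeline:
    path = _require(path, "laps")
    df = pd.read_csv(path)
    if "lap_start_s" not in df.columns:
        raise MalformedRowError("lap file must have a 'lap_start_s' column")
    return LapTimeline(df["lap_start_s"].to_numpy(float))


def write_laps(timeline: LapTimeline, path) -> None:
    pd.DataFrame({"lap_start_s": timeline.lap_starts}).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_session_meta(path) -> SessionMeta:
    path = _require(path, "session_meta")
    with open(path) as fh:
        raw = json.load(fh)
    return SessionMeta(**raw)


def write_session_meta(meta: SessionMeta, path) -> None:
    with open(path, "w") as fh:
        json.dump(meta.__dict__, fh, indent=1)


def read_session_dir(path) -> SessionBundle:
    """Load a full session bundle; any missing required file raises
    :class:`MissingStreamError`, the exclusion signal for the quality gate."""
    path = Path(path)
    return SessionBundle(
        session_id=path.name,
        phone=read_phone_stream(path / PHONE_FILE),
        rr=read_rr(path / RR_FILE),
        records=read_records(path / RECORDS_FILE),
        laps=read_laps(path / LAPS_FILE),
        meta=read_session_meta(path / META_FILE),
    )


def write_session_dir(bundle: SessionBundle, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_phone_stream(bundle.phone, path / PHONE_FILE)
    write_rr(bundle.rr, path / RR_FILE)
    write_records(bundle.records, path / RECORDS_FILE)
    write_laps(bundle.laps, path / LAPS_FILE)
    write_session_meta(bundle.meta, path / META_FILE)
    return path


# ---------------------------------------------------------------------------
# packed accelerometer and local-time handling


def unpack_packed_accel_field(text: str, line: Optional[int] = None) -> np.ndarray:
    """Decode one packed accelerometer field into 25 magnitude samples (m/s²).

    The field is a bracketed JSON array of exactly 25 values, the watch's
    25 Hz acceleration magnitudes for that one-second row."""
    try:
        values = json.loads(text)
    except (json.JSONDecodeError, TypeError) as exc:
        raise MalformedRowError(f"packed_accel is not valid JSON: {exc}", line)
    arr = np.asarray(values, dtype=float)
    if arr.shape != (PACKED_ACCEL_LEN,):
        raise MalformedRowError(
            f"packed_accel must hold exactly {PACKED_ACCEL_LEN} samples, "
            f"got shape {arr.shape}",
            line,
        )
    return arr


def unpack_packed_accel(row_second: float, packed: str) -> tuple[np.ndarray, np.ndarray]:
    """Unpack one record row's burst to timestamped 25 Hz samples.

    Returns (times, values): times start at the row's second and are spaced
    0.04 s (last sample at second + 0.96), values are the 25 magnitudes.
    """
    arr = unpack_packed_accel_field(packed)
    times = row_second + np.arange(PACKED_ACCEL_LEN) / PACKED_ACCEL_LEN
    return times, arr


def pack_accel(samples: np.ndarray) -> str:
    samples = np.asarray(samples, dtype=float)
    if samples.shape != (PACKED_ACCEL_LEN,):
        raise ValueError(f"expected {PACKED_ACCEL_LEN} samples")
    return json.dumps([round(float(v), 4) for v in samples])


def resolve_local_times(stream: WristRecordStream, meta: SessionMeta) -> pd.DatetimeIndex:
    """Convert HH:MM:SS local-time strings to absolute naive timestamps.

    Each time string is combined with the session date. A midnight
    crossover guard shifts any row whose time-of-day is earlier than its
    predecessor's forward by one day; more than one wrap in a session is
    physically impossible for these recordings and raises.
    """
    base = pd.Timestamp(meta.date)
    seconds = []
    for i, text in enumerate(stream.data["local_time"]):
        try:
            h, m, s = (int(part) for part in str(text).split(":"))
        except ValueError as exc:
            raise MalformedRowError(f"bad local_time {text!r}: {exc}", line=i + 1)
        if not (0 <= h < 24 and 0 <= m < 60 and 0 <= s < 60):
            raise MalformedRowError(f"local_time out of range: {text!r}", line=i + 1)
        seconds.append(h * 3600 + m * 60 + s)
    seconds = np.asarray(seconds, dtype=float)
    wraps = np.diff(seconds) < 0
    if wraps.sum() > 1:
        raise StreamOrderError("more than one midnight wrap in a single session")
    day_offset = np.concatenate([[0.0], np.cumsum(wraps) * 86400.0])
    absolute = base + pd.to_timedelta(seconds + day_offset, unit="s")
    idx = pd.DatetimeIndex(absolute)
    if len(idx) > 1 and not idx.is_monotonic_increasing:
        raise StreamOrderError("resolved local times are not monotone")
    return idx
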