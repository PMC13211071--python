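"""Forward model generating multi-device session bundles with known truth.

No public recording of this kind exists, so every downstream stage is
exercised against synthetic sessions that reproduce the statistical
structure of the real streams: per-state RR dynamics with a respiratory
modulation tone, a 1 Hz wrist record stream on the watch clock with
local-time strings and packed 25 Hz accelerometer bursts, a ~10 Hz phone
log on a second clock with a known offset, a three-swing sync-gesture
spike on both accelerometers, lap events at every comfort transition, and
optional mid-session phone data-loss gaps.

Default state-dependent levels follow the pilot's observed between-state
contrasts: mean RR 849 vs 778 ms (heart rate 70.7 vs 77.1 bpm), beat
SD 30 vs 24 ms (RMSSD ≈ 42 vs 34 ms for near-independent beats), wrist
temperature 31.9 vs 33.3 °C, sound 78.0 vs 77.4 dB, phone accelerometer
magnitude 0.42 vs 0.78 m/s². Slow within-session drifts and per-session
offsets keep the classes overlapping rather than trivially separable, as
in free-living data. Physiological realism beyond this (baroreflex,
IPFM-style point processes) is out of scope by design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .streams import (
    COMFORTABLE,
    PACKED_ACCEL_LEN,
    PHONE_COLUMNS,
    RECORD_COLUMNS,
    UNCOMFORTABLE,
    LapTimeline,
    PhoneStream,
    RRStream,
    SessionBundle,
    SessionMeta,
    WristRecordStream,
    pack_accel,
)

#: per-axis accel noise scale producing a 3D-magnitude mean of ~1 unit
_CHI3_MEAN = 2.0 * np.sqrt(2.0 / np.pi)

_START_TIMES = ["09:00:00", "13:30:00", "18:45:00", "07:15:00", "21:10:00", "11:05:00"]
_MIDNIGHT_START = "23:26:00"  # exercises the midnight crossover guard
_MIDNIGHT_MIN_DURATION_S = 2400.0


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the study conditions."""

    n_sessions: int = 18
    session_duration_s: float = 1500.0
    clock_offset_s: float = 3.0  # true watch-minus-phone offset
    sync_spike_time_s: float = 5.0  # last swing, phone elapsed clock
    #: explicit (start_s, state) segments; None derives a per-session layout
    comfort_segments: Optional[list[tuple[float, str]]] = None
    rr_mean_ms: dict[str, float] = field(
        default_factory=lambda: {COMFORTABLE: 849.0, UNCOMFORTABLE: 778.0}
    )
    rr_sd_ms: dict[str, float] = field(
        default_factory=lambda: {COMFORTABLE: 30.0, UNCOMFORTABLE: 24.0}
    )
    hf_mod_hz: float = 0.25  # respiratory modulation of RR
    hf_mod_depth_ms: float = 15.0
    temp_base_c: float = 31.9
    temp_state_delta_c: float = 1.4
    temp_drift_sd_c: float = 0.8  # slow within-session drift amplitude
    sound_base_db: float = 78.0
    sound_state_delta_db: float = -0.6
    sound_noise_db: float = 5.0
    sound_session_sd_db: float = 8.0  # between-session acoustic spread
    activity_level: dict[str, float] = field(
        default_factory=lambda: {COMFORTABLE: 0.42, UNCOMFORTABLE: 0.78}
    )
    hr_noise_bpm: float = 2.0
    hr_drift_sd_bpm: float = 4.0
    gap_at_s: Optional[float] = None  # phone data-loss gap start, watch clock
    gap_duration_s: float = 30.0
    single_class_fraction: float = 8.0 / 18.0
    artifact_indices: Optional[list[int]] = None  # RR artifact injection
    session_date: str = "2026-04-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_duration_s < 600:
            raise ValueError("sessions must last at least 600 s (10 min minimum)")
        if self.comfort_segments is not None:
            starts = [s for s, _ in self.comfort_segments]
            if starts != sorted(starts):
                raise ValueError("comfort segments must be sorted by start")
            if self.comfort_segments[0] != (0, COMFORTABLE) and self.comfort_segments[0] != (
                0.0,
                COMFORTABLE,
            ):
                raise ValueError(
                    "first segment must start at 0 in the comfortable state"
                )
        for mapping in (self.rr_mean_ms, self.rr_sd_ms):
            if any(v <= 0 for v in mapping.values()):
                raise ValueError("RR means and SDs must be positive")
        if self.gap_at_s is not None and not (
            0 < self.gap_at_s < self.session_duration_s
        ):
            raise ValueError("gap_at_s must fall inside the session")
        if not 0 <= self.single_class_fraction <= 1:
            raise ValueError("single_class_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator knows: the answers every stage must recover."""

    true_offset_s: float
    window_starts: np.ndarray  # 60 s grid on the watch clock
    window_labels: list[str]
    state_params: dict[str, dict[str, float]]
    comfort_segments: list[tuple[float, str]]
    gap_time_s: Optional[float]
    artifact_indices: list[int]
    sync_time_phone_s: float
    sync_time_garmin_s: float


def single_class_indices(n_sessions: int, fraction: float) -> set[int]:
    """Deterministic, evenly spread set of single-class session indices."""
    n_single = int(round(fraction * n_sessions))
    if n_single == 0:
        return set()
    return {int(np.floor(i * n_sessions / n_single)) for i in range(n_single)}


def _session_layout(config: SynthConfig, session_index: int, duration_s: float,
                    rng: np.random.Generator) -> list[tuple[float, str]]:
    """Comfort segments for one session when none are configured."""
    if config.comfort_segments is not None:
        return [(float(s), st) for s, st in config.comfort_segments]
    if session_index in single_class_indices(config.n_sessions, config.single_class_fraction):
        return [(0.0, COMFORTABLE)]
    n_seg = int(rng.integers(2, 5))
    cuts = duration_s * np.arange(1, n_seg) / n_seg
    # lap presses land on whole seconds, as the watch records them
    cuts = np.round(cuts + rng.uniform(-60.0, 60.0, size=len(cuts)))
    segments = [(0.0, COMFORTABLE)]
    for i, c in enumerate(np.sort(cuts)):
        state = UNCOMFORTABLE if i % 2 == 0 else COMFORTABLE
        segments.append((float(c), state))
    return segments


def _state_at(segments: list[tuple[float, str]], t: float) -> str:
    state = segments[0][1]
    for start, st in segments:
        if t >= start:
            state = st
        else:
            break
    return state


def _majority_window_labels(
    segments: list[tuple[float, str]], window_starts: np.ndarray,
    window_s: float, session_end_s: float,
) -> list[str]:
    """Per-window majority-overlap labels straight from the segment layout
    (independent of the pipeline's labelling code)."""
    edges = [s for s, _ in segments] + [max(session_end_s, window_starts[-1] + window_s)]
    labels = []
    for w0 in window_starts:
        w1 = w0 + window_s
        per_state: dict[str, float] = {}
        for i, (_, state) in enumerate(segments):
            ov = min(w1, edges[i + 1]) - max(w0, edges[i])
            if ov > 0:
                per_state[state] = per_state.get(state, 0.0) + ov
        best = max(per_state.values())
        winners = [st for st, v in per_state.items() if v == best]
        labels.append(winners[0] if len(winners) == 1 else _state_at(segments, w0))
    return labels


def _session_start_time(session_index: int, n_sessions: int) -> str:
    if n_sessions > 1 and session_index == n_sessions - 1:
        return _MIDNIGHT_START
    return _START_TIMES[session_index % len(_START_TIMES)]


def _session_duration(config: SynthConfig, session_index: int) -> float:
    if _session_start_time(session_index, config.n_sessions) == _MIDNIGHT_START:
        return max(config.session_duration_s, _MIDNIGHT_MIN_DURATION_S)
    return config.session_duration_s


def _ar1_drift(n: int, sd: float, tau_s: float, dt_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) drift with stationary SD ``sd`` and timescale tau."""
    if sd == 0:
        return np.zeros(n)
    rho = float(np.exp(-dt_s / tau_s))
    innov_sd = sd * np.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    noise = rng.normal(0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + noise[i]
    return x


def _generate_rr(config: SynthConfig, segments, duration_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Beat intervals covering the usable span, first beat at 90 s.

    Per-state Gaussian beats plus a sinusoid at the respiratory modulation
    frequency; intervals are clipped well inside (250, 2000) ms so the
    artifact filter only ever acts on explicitly injected outliers.
    """
    start = 90.0
    rr: list[float] = []
    t = start
    while t <= duration_s:
        state = _state_at(segments, t)
        value = (
            config.rr_mean_ms[state]
            + config.hf_mod_depth_ms * np.sin(2 * np.pi * config.hf_mod_hz * t)
            + rng.normal(0, config.rr_sd_ms[state])
        )
        value = float(np.clip(value, 340.0, 1490.0))
        rr.append(value)
        t += value / 1000.0
    rr_arr = np.asarray(rr)
    if config.artifact_indices:
        for pos, idx in enumerate(config.artifact_indices):
            if not 0 <= idx < len(rr_arr):
                raise ValueError(f"artifact index {idx} outside RR stream")
            rr_arr[idx] = 200.0 if pos % 2 == 0 else 1600.0
    return rr_arr


def _spike_profile(t: np.ndarray, spike_time: float, magnitude: float) -> np.ndarray:
    """Three arm swings 1 s apart ending at ``spike_time``; each swing is a
    narrow burst so the last one is an unambiguous peak."""
    out = np.zeros_like(t)
    for swing in (spike_time - 2.0, spike_time - 1.0, spike_time):
        out += magnitude * np.exp(-((t - swing) ** 2) / (2 * 0.03**2))
    return out


def _local_time_strings(start_time: str, n_seconds: int) -> list[str]:
    h, m, s = (int(p) for p in start_time.split(":"))
    base = h * 3600 + m * 60 + s
    out = []
    for k in range(n_seconds):
        tot = (base + k) % 86400
        out.append(f"{tot // 3600:02d}:{(tot % 3600) // 60:02d}:{tot % 60:02d}")
    return out


def generate_session(
    config: SynthConfig, session_index: int
) -> tuple[SessionBundle, GroundTruth]:
    """One synthetic session bundle plus its ground truth.

    Deterministic in (config.seed, session_index). The watch clock is the
    reference; the phone clock lags it by ``clock_offset_s`` (the sync
    gesture fires at ``sync_spike_time_s`` on the phone and at
    ``sync_spike_time_s + clock_offset_s`` on the watch).
    """
    rng = np.random.default_rng([config.seed, session_index])
    duration = _session_duration(config, session_index)
    segments = _session_layout(config, session_index, duration, rng)
    start_time = _session_start_time(session_index, config.n_sessions)
    offset = config.clock_offset_s
    spike_phone = config.sync_spike_time_s
    spike_garmin = spike_phone + offset

    # --- RR stream (watch clock, trimmed so first beat = usable start) ---
    rr_values = _generate_rr(config, segments, duration, rng)
    rr_stream = RRStream(rr_values.copy())

    # --- wrist record stream at 1 Hz on the watch clock, covering 0..duration ---
    n_rec = int(duration) + 1
    t_rec = np.arange(n_rec, dtype=float)
    states_rec = np.array([_state_at(segments, t) for t in t_rec])
    hr_base = np.array([60000.0 / config.rr_mean_ms[s] for s in states_rec])
    hr = (
        hr_base
        + _ar1_drift(n_rec, config.hr_drift_sd_bpm, 300.0, 1.0, rng)
        + rng.normal(0, config.hr_noise_bpm, n_rec)
    )
    temp = (
        config.temp_base_c
        + np.where(states_rec == UNCOMFORTABLE, config.temp_state_delta_c, 0.0)
        + _ar1_drift(n_rec, config.temp_drift_sd_c, 400.0, 1.0, rng)
        + rng.normal(0, 0.05, n_rec)
    )
    activity_rec = np.array([config.activity_level[s] for s in states_rec])
    packed = []
    for i in range(n_rec):
        burst = np.abs(rng.normal(activity_rec[i], activity_rec[i] / 3.0,
                                  PACKED_ACCEL_LEN))
        tt = t_rec[i] + np.arange(PACKED_ACCEL_LEN) / PACKED_ACCEL_LEN
        burst = burst + _spike_profile(tt, spike_garmin, 18.0)
        packed.append(pack_accel(burst))
    pressure = 1013.0 + _ar1_drift(n_rec, 0.3, 600.0, 1.0, rng)
    altitude = 30.0 + _ar1_drift(n_rec, 0.5, 600.0, 1.0, rng)
    indoor = session_index % 3 != 2
    gps_speed = np.full(n_rec, np.nan)
    if not indoor:
        moving = rng.random(n_rec) < 0.4
        gps_speed[moving] = np.abs(rng.normal(1.3, 0.4, int(moving.sum())))
    heading = np.mod(
        rng.uniform(0, 360) + np.cumsum(rng.normal(0, 2.0, n_rec)), 360.0
    )
    records = WristRecordStream(
        pd.DataFrame(
            {
                "local_time": _local_time_strings(start_time, n_rec),
                "hr": np.round(hr, 1),
                "wrist_temp": np.round(temp, 2),
                "packed_accel": packed,
                "pressure": np.round(pressure, 2),
                "altitude": np.round(altitude, 2),
                "gps_speed": np.round(gps_speed, 2),
                "heading": np.round(heading, 1),
            },
            columns=RECORD_COLUMNS,
        )
    )

    # --- phone stream at 10 Hz on the phone clock ---
    t_phone = np.arange(0.0, duration - offset + 1e-9, 0.1)
    t_on_garmin = t_phone + offset
    states_ph = np.array([_state_at(segments, t) for t in t_on_garmin])
    axis_sd = np.array([config.activity_level[s] for s in states_ph]) / _CHI3_MEAN
    accel = rng.normal(0, 1, (len(t_phone), 3)) * axis_sd[:, None]
    accel[:, 0] += _spike_profile(t_phone, spike_phone, 20.0)
    gyro = rng.normal(0, 0.1, (len(t_phone), 3)) * (1 + axis_sd[:, None])
    grav = np.tile([0.0, 0.0, 9.81], (len(t_phone), 1)) + rng.normal(
        0, 0.01, (len(t_phone), 3)
    )
    mag = np.tile([20.0, 5.0, -45.0], (len(t_phone), 1)) + rng.normal(
        0, 1.0, (len(t_phone), 3)
    )
    sound_session = rng.normal(0, config.sound_session_sd_db)
    sound = (
        config.sound_base_db
        + sound_session
        + np.where(states_ph == UNCOMFORTABLE, config.sound_state_delta_db, 0.0)
        + rng.normal(0, config.sound_noise_db, len(t_phone))
    )
    lux = np.abs(rng.normal(4.0, 1.5, len(t_phone)))
    phone_df = pd.DataFrame(
        np.column_stack(
            [t_phone, accel, gyro, grav, mag, sound[:, None], lux[:, None]]
        ),
        columns=PHONE_COLUMNS,
    ).round(6)

    gap_time = None
    if config.gap_at_s is not None:
        in_gap = (t_on_garmin >= config.gap_at_s) & (
            t_on_garmin < config.gap_at_s + config.gap_duration_s
        )
        # truth records the last surviving sample before the gap, which is
        # where the pipeline's trimming rule actually cuts
        gap_time = float(t_on_garmin[t_on_garmin < config.gap_at_s].max())
        phone_df = phone_df.loc[~in_gap].reset_index(drop=True)
    phone = PhoneStream(phone_df)

    # --- laps and metadata ---
    laps = LapTimeline(np.array([s for s, _ in segments], dtype=float))
    meta = SessionMeta(
        date=config.session_date,
        start_time=start_time,
        location_name=f"synthetic-site-{session_index:02d}",
        lat=-37.82 + 0.01 * session_index,
        lon=144.96 + 0.01 * session_index,
        indoor=indoor,
        notes="synthetic session",
    )
    bundle = SessionBundle(
        session_id=f"session-{session_index:02d}",
        phone=phone,
        rr=rr_stream,
        records=records,
        laps=laps,
        meta=meta,
    )

    # --- ground truth ---
    usable_start = 90.0
    usable_end = gap_time if gap_time is not None else duration - 90.0
    n_windows = int(np.floor((usable_end - usable_start) / 60.0))
    window_starts = usable_start + 60.0 * np.arange(n_windows)
    truth = GroundTruth(
        true_offset_s=offset,
        window_starts=window_starts,
        window_labels=_majority_window_labels(segments, window_starts, 60.0, duration),
        state_params={
            COMFORTABLE: {
                "rr_mean_ms": config.rr_mean_ms[COMFORTABLE],
                "rr_sd_ms": config.rr_sd_ms[COMFORTABLE],
            },
            UNCOMFORTABLE: {
                "rr_mean_ms": config.rr_mean_ms[UNCOMFORTABLE],
                "rr_sd_ms": config.rr_sd_ms[UNCOMFORTABLE],
            },
        },
        comfort_segments=segments,
        gap_time_s=gap_time,
        artifact_indices=list(config.artifact_indices or []),
        sync_time_phone_s=spike_phone,
        sync_time_garmin_s=spike_garmin,
    )
    return bundle, truth


def generate_cohort(config: SynthConfig) -> list[tuple[SessionBundle, GroundTruth]]:
    """All sessions of a cohort; per-session seeds fan out deterministically,
    and exactly round(single_class_fraction × n_sessions) sessions carry a
    single comfort state."""
    if config.n_sessions < 2:
        raise ValueError("a cohort needs at least two sessions")
    return [generate_session(config, i) for i in range(config.n_sessions)]


def strongly_separated_config(**overrides) -> SynthConfig:
    """Cohort whose between-state effects dwarf the within-state noise
    (≥ 3 SD on temperature, sound and movement): any competent classifier
    should approach perfect discrimination on its valid folds."""
    base = dict(
        rr_mean_ms={COMFORTABLE: 880.0, UNCOMFORTABLE: 680.0},
        rr_sd_ms={COMFORTABLE: 30.0, UNCOMFORTABLE: 22.0},
        temp_state_delta_c=4.0,
        temp_drift_sd_c=0.3,
        sound_state_delta_db=15.0,
        sound_noise_db=2.0,
        sound_session_sd_db=2.0,
        activity_level={COMFORTABLE: 0.3, UNCOMFORTABLE: 2.0},
        hr_drift_sd_bpm=1.0,
    )
    base.update(overrides)
    return SynthConfig(**base)


def sound_driven_config(**overrides) -> SynthConfig:
    """Cohort where only the acoustic level differs between states; every
    other state-dependent parameter is flat, so any recovered signal must
    come from the sound features."""
    base = dict(
        rr_mean_ms={COMFORTABLE: 820.0, UNCOMFORTABLE: 820.0},
        rr_sd_ms={COMFORTABLE: 27.0, UNCOMFORTABLE: 27.0},
        temp_state_delta_c=0.0,
        sound_state_delta_db=15.0,
        sound_noise_db=2.0,
        sound_session_sd_db=0.0,
        activity_level={COMFORTABLE: 0.5, UNCOMFORTABLE: 0.5},
    )
    base.update(overrides)
    return SynthConfig(**base)


def replace(config: SynthConfig, **overrides) -> SynthConfig:
    """Convenience wrapper over dataclasses.replace."""
    return dataclasses.replace(config, **overrides)
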