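"""Per-window kinematic, acoustic, magnetic, cardiac-record and thermal features.

Phone features come from the ~10 Hz sensor log (600 samples per nominal
60 s window, 480 minimum — fewer means the window fell in a data-loss gap
and is discarded). Watch features come from the 1 Hz record stream and the
unpacked 25 Hz wrist accelerometer bursts. All vector statistics operate
on Euclidean magnitudes, so they are invariant to sensor-frame rotation;
sound levels are used in dB exactly as recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streams import PhoneStream, WristRecordStream, unpack_packed_accel

MIN_PHONE_SAMPLES = 480

CONTEXT_FEATURES = [
    "hr_mean", "hr_sd", "hr_min", "hr_max", "hr_reserve_mean",
    "temp_mean", "temp_sd", "temp_rate_of_change",
    "wrist_accel_mag_mean", "wrist_accel_mag_sd", "wrist_accel_mag_max",
    "accel_mag_mean", "accel_mag_sd", "accel_mag_min", "accel_mag_max",
    "ax_mean", "ax_sd", "ay_mean", "ay_sd", "az_mean", "az_sd",
    "jerk_mean", "jerk_sd", "jerk_max",
    "gyro_mag_mean", "gyro_mag_sd", "gyro_mag_max",
    "gyro_x_mean", "gyro_x_sd", "gyro_y_mean", "gyro_y_sd",
    "gyro_z_mean", "gyro_z_sd",
    "sound_mean", "sound_sd", "sound_min", "sound_max",
    "mag_mag_mean", "mag_mag_sd", "mag_mag_min", "mag_mag_max",
]

#: extra features computed only for the exclusion audit, never modelled
AUDIT_FEATURES = [
    "grav_x_mean", "grav_y_mean", "grav_z_mean",
    "mag_x_mean", "mag_y_mean", "mag_z_mean",
    "lux_mean", "lux_sd",
    "pressure_mean", "pressure_rate",
    "altitude_mean", "altitude_rate",
    "gps_speed_mean",
    "heading_circ_var",
    "gyro_mag_min",
]


@dataclass
class HrReserveParams:
    """Personal heart-rate range for the reserve normalisation:
    reserve = (HR − HR_rest) / (HR_max − HR_rest) × 100."""

    hr_max: float = 203.0  # bpm, from the wearer's watch profile
    hr_rest: float = 60.0  # bpm, standard approximation for a fit young male

    def __post_init__(self) -> None:
        if self.hr_max <= self.hr_rest:
            raise ValueError("hr_max must exceed hr_rest")


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _slope_per_minute(t_s: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y against time, per minute."""
    if len(y) < 2 or np.ptp(t_s) == 0:
        return float("nan")
    slope_per_s = np.polyfit(t_s, y, 1)[0]
    return float(slope_per_s * 60.0)


def phone_window_features(
    stream: PhoneStream,
    window: tuple[float, float],
    aligned_times: np.ndarray | None = None,
    audit: bool = False,
) -> dict[str, float] | None:
    """Kinematic, acoustic and magnetic block for one [start, end) window.

    ``aligned_times`` carries the phone timestamps shifted onto the watch
    clock; omit it to window on raw phone elapsed time. Returns None when
    the window holds fewer than 480 samples (data-gap periods contribute
    near-zero samples and are discarded this way). Jerk uses the actual
    per-sample time step, not the nominal 0.1 s.
    """
    t = stream.t_elapsed if aligned_times is None else np.asarray(aligned_times, float)
    w0, w1 = window
    sel = (t >= w0) & (t < w1)
    n = int(sel.sum())
    if n < MIN_PHONE_SAMPLES:
        return None
    sub = stream.data.loc[sel]
    t_sel = t[sel]

    accel = sub[["ax", "ay", "az"]].to_numpy(float)
    accel_mag = np.linalg.norm(accel, axis=1)
    gyro = sub[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float)
    gyro_mag = np.linalg.norm(gyro, axis=1)
    mag = sub[["mag_x", "mag_y", "mag_z"]].to_numpy(float)
    mag_mag = np.linalg.norm(mag, axis=1)
    sound = sub["sound"].to_numpy(float)
    jerk = np.abs(np.diff(accel_mag)) / np.diff(t_sel)

    out = {
        "accel_mag_mean": float(accel_mag.mean()),
        "accel_mag_sd": _sd(accel_mag),
        "accel_mag_min": float(accel_mag.min()),
        "accel_mag_max": float(accel_mag.max()),
        "ax_mean": float(accel[:, 0].mean()), "ax_sd": _sd(accel[:, 0]),
        "ay_mean": float(accel[:, 1].mean()), "ay_sd": _sd(accel[:, 1]),
        "az_mean": float(accel[:, 2].mean()), "az_sd": _sd(accel[:, 2]),
        "jerk_mean": float(jerk.mean()),
        "jerk_sd": _sd(jerk),
        "jerk_max": float(jerk.max()),
        "gyro_mag_mean": float(gyro_mag.mean()),
        "gyro_mag_sd": _sd(gyro_mag),
        "gyro_mag_max": float(gyro_mag.max()),
        "gyro_x_mean": float(gyro[:, 0].mean()), "gyro_x_sd": _sd(gyro[:, 0]),
        "gyro_y_mean": float(gyro[:, 1].mean()), "gyro_y_sd": _sd(gyro[:, 1]),
        "gyro_z_mean": float(gyro[:, 2].mean()), "gyro_z_sd": _sd(gyro[:, 2]),
        "sound_mean": float(sound.mean()),
        "sound_sd": _sd(sound),
        "sound_min": float(sound.min()),
        "sound_max": float(sound.max()),
        "mag_mag_mean": float(mag_mag.mean()),
        "mag_mag_sd": _sd(mag_mag),
        "mag_mag_min": float(mag_mag.min()),
        "mag_mag_max": float(mag_mag.max()),
        "n_phone_samples": float(n),
    }
    if audit:
        grav = sub[["grav_x", "grav_y", "grav_z"]].to_numpy(float)
        lux = sub["lux"].to_numpy(float)
        out.update({
            "grav_x_mean": float(grav[:, 0].mean()),
            "grav_y_mean": float(grav[:, 1].mean()),
            "grav_z_mean": float(grav[:, 2].mean()),
            "mag_x_mean": float(mag[:, 0].mean()),
            "mag_y_mean": float(mag[:, 1].mean()),
            "mag_z_mean": float(mag[:, 2].mean()),
            "lux_mean": float(lux.mean()),
            "lux_sd": _sd(lux),
            "gyro_mag_min": float(gyro_mag.min()),
        })
    return out


def heart_rate_features(
    records: WristRecordStream,
    record_times: np.ndarray,
    window: tuple[float, float],
    params: HrReserveParams | None = None,
) -> dict[str, float] | None:
    """HR statistics and heart-rate reserve over one window.

    Reserve normalises the window's mean HR to the wearer's personal
    physiological range, so 0% is rest and 100% is maximum.
    """
    params = params or HrReserveParams()
    t = np.asarray(record_times, dtype=float)
    sel = (t >= window[0]) & (t < window[1])
    if not sel.any():
        return None
    hr = records.data["hr"].to_numpy(float)[sel]
    hr_mean = float(hr.mean())
    return {
        "hr_mean": hr_mean,
        "hr_sd": _sd(hr),
        "hr_min": float(hr.min()),
        "hr_max": float(hr.max()),
        "hr_reserve_mean": (hr_mean - params.hr_rest)
        / (params.hr_max - params.hr_rest) * 100.0,
    }


def temperature_features(
    records: WristRecordStream,
    record_times: np.ndarray,
    window: tuple[float, float],
) -> dict[str, float] | None:
    """Wrist temperature mean, SD and least-squares rate of change (°C/min).

    The rate of change captures thermal transition dynamics the mean alone
    cannot: moving between environments shows up as a slope before the
    window mean stabilises. A least-squares slope is used rather than
    (last − first)/Δt for robustness to single-sample noise at 1 Hz.
    """
    t = np.asarray(record_times, dtype=float)
    sel = (t >= window[0]) & (t < window[1])
    if not sel.any():
        return None
    temp = records.data["wrist_temp"].to_numpy(float)[sel]
    return {
        "temp_mean": float(temp.mean()),
        "temp_sd": _sd(temp),
        "temp_rate_of_change": _slope_per_minute(t[sel], temp)
        if sel.sum() >= 2 else float("nan"),
    }


def wrist_accel_features(
    records: WristRecordStream,
    record_times: np.ndarray,
    window: tuple[float, float],
) -> dict[str, float] | None:
    """Magnitude statistics of the unpacked 25 Hz wrist accelerometer.

    Each 1 s record row unpacks to 25 samples (≈1500 per 60 s window)."""
    t = np.asarray(record_times, dtype=float)
    sel = np.nonzero((t >= window[0]) & (t < window[1]))[0]
    if len(sel) == 0:
        return None
    mags = []
    packed = records.data["packed_accel"].to_numpy()
    for i in sel:
        _, values = unpack_packed_accel(t[i], packed[i])
        mags.append(values)
    m = np.concatenate(mags)
    return {
        "wrist_accel_mag_mean": float(m.mean()),
        "wrist_accel_mag_sd": _sd(m),
        "wrist_accel_mag_max": float(m.max()),
    }


def heading_circular_variance(headings_deg: np.ndarray) -> float:
    """1 − mean resultant length of the heading unit vectors, in [0, 1].

    Unit-vector averaging handles the 0/360° boundary correctly: headings
    of 359° and 1° average to nearly zero variance. Computed for the
    exclusion audit only — direction change captures activity context, not
    comfort — and never enters the modelled schema.
    """
    h = np.radians(np.asarray(headings_deg, dtype=float))
    if len(h) == 0:
        raise ValueError("needs at least one heading")
    resultant = np.hypot(np.mean(np.cos(h)), np.mean(np.sin(h)))
    return float(1.0 - resultant)


def record_audit_features(
    records: WristRecordStream,
    record_times: np.ndarray,
    window: tuple[float, float],
) -> dict[str, float]:
    """Audit-only record-stream features (pressure/altitude rates, GPS
    speed, heading variance); nullable GPS speed stays missing, never 0."""
    t = np.asarray(record_times, dtype=float)
    sel = (t >= window[0]) & (t < window[1])
    sub = records.data.loc[sel]
    t_sel = t[sel]
    gps = pd.to_numeric(sub["gps_speed"], errors="coerce").to_numpy(float)
    out = {
        "pressure_mean": float(sub["pressure"].astype(float).mean()),
        "pressure_rate": _slope_per_minute(t_sel, sub["pressure"].to_numpy(float)),
        "altitude_mean": float(sub["altitude"].astype(float).mean()),
        "altitude_rate": _slope_per_minute(t_sel, sub["altitude"].to_numpy(float)),
        "gps_speed_mean": float(np.nanmean(gps)) if np.isfinite(gps).any() else float("nan"),
        "heading_circ_var": heading_circular_variance(sub["heading"].to_numpy(float)),
    }
    return out


def extract_context_windows(
    phone: PhoneStream,
    records: WristRecordStream,
    grid,
    phone_aligned_times: np.ndarray,
    record_times: np.ndarray,
    params: HrReserveParams | None = None,
    audit: bool = False,
) -> dict[int, dict[str, float]]:
    """Context feature rows per grid window, keyed by window index.

    A row is emitted whenever the phone block survives the 480-sample
    minimum; record-stream blocks that have no samples stay missing within
    the row rather than suppressing it.
    """
    rows: dict[int, dict[str, float]] = {}
    for idx, win in enumerate(grid.intervals()):
        phone_block = phone_window_features(
            phone, win, aligned_times=phone_aligned_times, audit=audit
        )
        if phone_block is None:
            continue
        row = dict(phone_block)
        for block in (
            heart_rate_features(records, record_times, win, params),
            temperature_features(records, record_times, win),
            wrist_accel_features(records, record_times, win),
        ):
            if block:
                row.update(block)
        if audit:
            row.update(record_audit_features(records, record_times, win))
        rows[idx] = row
    return rows
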