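"""Per-window heart-rate-variability features from the RR-interval stream.

The chest strap delivers RR intervals in milliseconds with no timestamps.
Artifact rejection keeps intervals in the physiologically plausible
333–1500 ms range (180 down to 40 bpm); beat times are reconstructed by
anchoring the first kept beat to the start of the usable session window
and cumulatively summing intervals. Features are computed on
non-overlapping 60 s windows — the ultra-short-term HRV regime, a
deliberate trade of spectral precision for the temporal resolution needed
to track comfort transitions:

* time domain: mean RR, SDNN, RMSSD, SDSD, pNN50, mean HR;
* frequency domain via the Lomb–Scargle periodogram evaluated directly on
  the irregular beat times (no interpolation): LF 0.04–0.15 Hz, HF
  0.15–0.40 Hz, their sum and ratio. VLF is not computed — 60 s windows
  cannot resolve it;
* nonlinear: Poincaré SD1/SD2 and sample entropy (m=2, r=0.2·SD,
  Chebyshev distance, self-matches excluded).

Windows with fewer than 30 beats after artifact removal are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .streams import RRStream
from .sync import WindowGrid

RR_MIN_MS = 333.0
RR_MAX_MS = 1500.0
MIN_BEATS_PER_WINDOW = 30

LF_BAND = (0.04, 0.15)  # Hz, half-open [lo, hi)
HF_BAND = (0.15, 0.40)  # Hz, closed [lo, hi]
FREQ_STEP_HZ = 0.004

HRV_FEATURES = [
    "mean_rr", "sdnn", "rmssd", "sdsd", "pnn50", "mean_hr",
    "lf_power", "hf_power", "lf_hf_ratio", "total_power",
    "sd1", "sd2", "sd1_sd2_ratio", "sample_entropy",
]


class EmptySeriesError(Exception):
    """Artifact rejection removed every beat."""


@dataclass
class BeatSeries:
    """Artifact-filtered RR intervals with reconstructed absolute beat times.

    ``beat_time[i+1] - beat_time[i] == rr[i+1] / 1000``: each interval is
    the gap *preceding* its beat, and the first beat is anchored to the
    usable-window start.
    """

    rr: np.ndarray  # ms
    beat_time: np.ndarray  # s, aligned clock

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        if self.rr.shape != self.beat_time.shape:
            raise ValueError("rr and beat_time must have equal length")
        if len(self.rr) > 1 and not np.all(np.diff(self.beat_time) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.rr)


def reject_artifacts(rr: RRStream | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop RR intervals outside [333, 1500] ms (bounds kept, inclusive).

    Returns (filtered, keep_mask). Raises :class:`EmptySeriesError` when
    nothing survives.
    """
    values = rr.rr if isinstance(rr, RRStream) else np.asarray(rr, dtype=float)
    if len(values) == 0:
        raise EmptySeriesError("empty RR stream")
    mask = (values >= RR_MIN_MS) & (values <= RR_MAX_MS)
    if not mask.any():
        raise EmptySeriesError("all RR intervals rejected as artifacts")
    return values[mask], mask


def reconstruct_beat_times(rr: np.ndarray, window_start_s: float) -> BeatSeries:
    """Anchor the first beat to the usable-window start and cumulate.

    Valid because the RR stream is already trimmed so its first beat is the
    first beat after start padding.
    """
    rr = np.asarray(rr, dtype=float)
    times = window_start_s + np.concatenate([[0.0], np.cumsum(rr[1:]) / 1000.0])
    return BeatSeries(rr=rr, beat_time=times)


def time_domain(rr: np.ndarray) -> dict[str, float]:
    """Time-domain features for one window's RR sequence (ms).

    SDNN and SDSD are n−1 sample standard deviations; RMSSD divides by the
    number of successive differences. Mean HR is derived from the mean RR.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 2:
        raise ValueError("time-domain features need at least two beats")
    diffs = np.diff(rr)
    mean_rr = float(np.mean(rr))
    return {
        "mean_rr": mean_rr,
        "sdnn": float(np.std(rr, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "sdsd": float(np.std(diffs, ddof=1)) if len(diffs) > 1 else float("nan"),
        "pnn50": float(100.0 * np.mean(np.abs(diffs) > 50.0)),
        "mean_hr": 60000.0 / mean_rr,
    }


def lomb_scargle_psd(
    beat_time_s: np.ndarray, rr_ms: np.ndarray, freqs_hz: np.ndarray
) -> np.ndarray:
    """Lomb–Scargle power spectral density of the mean-centred RR sequence.

    Scaled as 2·P/n so a full-band integral approximates the series
    variance contribution (ms²); the absolute scale is a convention, band
    ratios are what carry signal at this window length.
    """
    x = np.asarray(rr_ms, dtype=float)
    x = x - x.mean()
    omega = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float)
    power = lombscargle(np.asarray(beat_time_s, dtype=float), x, omega)
    return 2.0 * power / len(x)


def spectral_power(beats: BeatSeries) -> dict[str, float]:
    """Band-integrated LF/HF power from the Lomb–Scargle periodogram.

    The grid spans [0.04, 0.40] Hz at 0.004 Hz spacing (≥ 27 points inside
    LF); band powers are trapezoidal integrals, LF over [0.04, 0.15) and
    HF over [0.15, 0.40]. The LF/HF ratio is missing when HF is zero.
    """
    if len(beats) < MIN_BEATS_PER_WINDOW:
        raise ValueError(
            f"spectral features need >= {MIN_BEATS_PER_WINDOW} beats"
        )
    freqs = np.arange(LF_BAND[0], HF_BAND[1] + FREQ_STEP_HZ / 2, FREQ_STEP_HZ)
    psd = lomb_scargle_psd(beats.beat_time, beats.rr, freqs)
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    lf = float(np.trapezoid(psd[lf_mask], freqs[lf_mask]))
    hf = float(np.trapezoid(psd[hf_mask], freqs[hf_mask]))
    return {
        "lf_power": lf,
        "hf_power": hf,
        "total_power": lf + hf,
        "lf_hf_ratio": lf / hf if hf > 0 else float("nan"),
    }


def poincare(rr: np.ndarray) -> dict[str, float]:
    """Poincaré plot dispersion: SD1 (perpendicular to the identity line),
    SD2 (parallel), and their ratio.

    SD1 = sqrt(1/2)·SDSD exactly; SD2 = sqrt(2·SDNN² − SDSD²/2) with a
    floor at zero against floating-point noise on near-degenerate windows.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 3:
        raise ValueError("Poincaré features need at least three beats")
    sdnn = np.std(rr, ddof=1)
    sdsd = np.std(np.diff(rr), ddof=1)
    sd1 = float(np.sqrt(0.5) * sdsd)
    sd2 = float(np.sqrt(max(2.0 * sdnn**2 - 0.5 * sdsd**2, 0.0)))
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd1_sd2_ratio": sd1 / sd2 if sd2 > 0 else float("nan"),
    }


def sample_entropy(rr: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy, −ln(A/B), of one window's RR sequence.

    Template matches use Chebyshev distance at tolerance r = r_factor × SD
    of the window's RR series, counting ordered pairs i < j with
    self-matches excluded; B counts length-m matches and A length-(m+1).
    Degenerate cases (zero SD, no matches at either length) return NaN —
    the value propagates as missing, never as zero.
    """
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    if n < m + 2:
        raise ValueError(f"sample entropy needs at least {m + 2} beats")
    sd = np.std(rr, ddof=1)
    if sd == 0:
        return float("nan")
    r = r_factor * sd

    def _count(length: int) -> int:
        k = n - length + 1
        templates = np.lib.stride_tricks.sliding_window_view(rr, length)
        # pairwise Chebyshev distances over the k templates
        dist = np.max(
            np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1
        )
        within = dist <= r
        return int((np.sum(within) - k) // 2)  # upper triangle, no self-matches

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def window_features(rr: np.ndarray, beat_series: BeatSeries) -> dict[str, float]:
    """All HRV features for one window (the caller slices beats to windows)."""
    out = time_domain(rr)
    out.update(spectral_power(beat_series))
    out.update(poincare(rr))
    out["sample_entropy"] = sample_entropy(rr)
    out["n_beats"] = float(len(rr))
    return out


def extract_hrv_windows(beats: BeatSeries, grid: WindowGrid) -> dict[int, dict[str, float]]:
    """HRV feature rows per grid window, keyed by window index.

    A beat belongs to window [start, start+60) by its reconstructed beat
    time (half-open: a beat at exactly start+60 belongs to the next
    window). Windows with fewer than 30 beats after artifact removal yield
    no row.
    """
    rows: dict[int, dict[str, float]] = {}
    for idx, (w0, w1) in enumerate(grid.intervals()):
        sel = (beats.beat_time >= w0) & (beats.beat_time < w1)
        if int(sel.sum()) < MIN_BEATS_PER_WINDOW:
            continue
        rr_win = beats.rr[sel]
        sub = BeatSeries(rr=rr_win, beat_time=beats.beat_time[sel])
        rows[idx] = window_features(rr_win, sub)
    return rows
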