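"""Quality gating, clock alignment, gap/padding handling and the window grid.

Each session records on two independent clocks: the watch (reference) and
the phone. A three-arm-swing gesture at session start produces a
high-magnitude accelerometer spike on both devices; the elapsed time of the
last swing on each clock forms a pair of sync anchors, and phone timestamps
are shifted onto the watch clock by their difference. Downstream, the
usable portion of the session is trimmed for boundary artifacts (90 s of
padding) and phone data-loss gaps (first inter-sample gap over 5 s), then
cut into non-overlapping 60 s windows labelled from the lap timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .streams import COMFORTABLE, LapTimeline, PhoneStream

#: padding removed at session boundaries to drop transient behaviour, s
DEFAULT_PAD_S = 90.0
#: first phone inter-sample gap above this is a data-loss event, s
DEFAULT_GAP_THRESHOLD_S = 5.0
#: non-overlapping analysis window length, s
WINDOW_S = 60.0


class SyncError(Exception):
    """Base class for alignment failures."""


class NoSyncDetectedError(SyncError):
    """No sync-gesture spike found; the session needs manual anchors."""


class SessionTooShortError(SyncError):
    """Usable window shorter than one analysis window."""


@dataclass
class SyncAnchors:
    """Elapsed times of the sync gesture on each clock.

    ``source`` records whether the anchors were entered manually or found
    by the automatic spike detector.
    """

    t_garmin_sync: float
    t_oppo_sync: float
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.t_garmin_sync < 0 or self.t_oppo_sync < 0:
            raise ValueError("sync anchors must be non-negative")

    @property
    def offset_s(self) -> float:
        """Watch-minus-phone clock offset implied by the anchors."""
        return self.t_garmin_sync - self.t_oppo_sync


@dataclass
class SyncDetection:
    """Result of the automatic spike detector (advisory, not authoritative)."""

    time_s: float
    peak_ratio: float  # peak magnitude / (k * median magnitude)
    confident: bool


@dataclass
class UsableWindow:
    start_s: float
    end_s: float
    gap_detected: bool = False
    gap_time_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise SessionTooShortError(
                f"usable window empty: [{self.start_s}, {self.end_s}]"
            )
        if self.gap_detected and self.gap_time_s is not None:
            if self.end_s > self.gap_time_s:
                raise ValueError("usable window extends past the data-loss gap")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class WindowGrid:
    """Contiguous non-overlapping [start, start+60) windows on the aligned clock."""

    starts: np.ndarray
    window_s: float = WINDOW_S
    labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float)

    def __len__(self) -> int:
        return len(self.starts)

    def intervals(self) -> list[tuple[float, float]]:
        return [(s, s + self.window_s) for s in self.starts]


def detect_gap(
    stream: PhoneStream, threshold_s: float = DEFAULT_GAP_THRESHOLD_S
) -> Optional[float]:
    """Timestamp of the last good sample before the FIRST gap > threshold.

    Returns None when no inter-sample spacing exceeds the threshold. Only
    the first gap matters: everything after it is discarded anyway.
    """
    t = stream.t_elapsed
    if len(t) < 2:
        raise ValueError("gap detection needs at least two samples")
    gaps = np.diff(t)
    over = np.nonzero(gaps > threshold_s)[0]
    if len(over) == 0:
        return None
    return float(t[over[0]])


def align_clocks(anchors: SyncAnchors, phone_times: np.ndarray) -> np.ndarray:
    """Shift phone elapsed times onto the watch clock.

    The sync gesture happened at ``t_oppo_sync`` on the phone and
    ``t_garmin_sync`` on the watch, so adding their difference maps the
    anchor onto the anchor; the shift is exactly invertible by swapping the
    anchors.
    """
    return np.asarray(phone_times, dtype=float) + anchors.offset_s


def detect_sync_spike(
    times: np.ndarray,
    magnitudes: np.ndarray,
    search_window_s: float = 20.0,
    k: float = 5.0,
    gesture_span_s: float = 10.0,
) -> SyncDetection:
    """Find the sync gesture in an accelerometer magnitude stream.

    Looks for peaks at least ``k`` times the median magnitude within the
    first ``search_window_s`` seconds and returns the time of the LAST such
    peak — the last arm swing is the shared reference instant on both
    devices. The detection is flagged low-confidence (for manual anchor
    entry) when the qualifying peaks spread over more than
    ``gesture_span_s``, which a compact three-swing gesture never does.

    Raises :class:`NoSyncDetectedError` when no peak clears the threshold.
    """
    times = np.asarray(times, dtype=float)
    magnitudes = np.asarray(magnitudes, dtype=float)
    sel = times <= times[0] + search_window_s
    if sel.sum() < 3:
        raise NoSyncDetectedError("stream does not cover the search window")
    t, m = times[sel], magnitudes[sel]
    med = float(np.median(m))
    threshold = k * med if med > 0 else k * (float(np.mean(m)) or 1.0)
    peaks, props = find_peaks(m, height=threshold)
    # a spike in the very first or last sample has no neighbours; check ends
    for edge in (0, len(m) - 1):
        if m[edge] >= threshold and edge not in peaks:
            peaks = np.append(peaks, edge)
    if len(peaks) == 0:
        raise NoSyncDetectedError(
            f"no accelerometer peak above {k}x median in the first "
            f"{search_window_s:g} s"
        )
    peaks = np.sort(peaks)
    last = peaks[-1]
    span = float(t[last] - t[peaks[0]])
    ratio = float(m[last] / threshold)
    return SyncDetection(
        time_s=float(t[last]),
        peak_ratio=ratio,
        confident=span <= gesture_span_s,
    )


def compute_usable_window(
    phone_end_s: float,
    record_end_s: float,
    gap_time_s: Optional[float] = None,
    pad_s: float = DEFAULT_PAD_S,
    session_start_s: float = 0.0,
) -> UsableWindow:
    """Trim the session to its analysable span on the aligned clock.

    The raw end is the earlier of the last phone sample and the last wrist
    record, so dead recording time on either device is excluded. Without a
    gap, ``pad_s`` is removed from both ends. With a data-loss gap the
    session ends at the last good sample before the gap and only start
    padding applies — the recording died mid-session without the subject's
    awareness, so there are no end-of-session behavioural artifacts to trim.
    """
    end = min(float(phone_end_s), float(record_end_s))
    start = session_start_s + pad_s
    if gap_time_s is not None:
        end = min(end, float(gap_time_s))
        usable = UsableWindow(start, end, gap_detected=True, gap_time_s=float(gap_time_s)) \
            if end > start else None
    else:
        end = end - pad_s
        usable = UsableWindow(start, end) if end > start else None
    if usable is None or usable.duration_s < WINDOW_S:
        raise SessionTooShortError(
            f"usable duration below one {WINDOW_S:g} s window"
        )
    return usable


def lap_durations(timeline: LapTimeline, session_end_s: float) -> np.ndarray:
    """Per-lap durations from consecutive start times.

    The watch stores laps as start timestamps only; lap i runs to lap
    i+1's start, and the final lap runs to the session end.
    """
    starts = timeline.lap_starts
    if session_end_s <= starts[-1]:
        raise ValueError("session end must fall after the last lap start")
    edges = np.concatenate([starts, [float(session_end_s)]])
    durations = np.diff(edges)
    if np.any(durations <= 0):
        raise ValueError("zero-length lap")
    return durations


def build_window_grid(usable: UsableWindow, window_s: float = WINDOW_S) -> WindowGrid:
    """Anchor the 60 s grid at the usable-window start; a trailing partial
    window is discarded."""
    n = int(np.floor(usable.duration_s / window_s))
    if n == 0:
        raise SessionTooShortError("no complete window fits the usable span")
    starts = usable.start_s + window_s * np.arange(n)
    return WindowGrid(starts=starts, window_s=window_s)


def state_intervals(
    timeline: LapTimeline, session_end_s: float
) -> list[tuple[float, float, str]]:
    """(start, end, state) per lap after corrections, covering to session end."""
    starts, states = timeline.effective_boundaries()
    if session_end_s <= starts[-1]:
        raise ValueError("session end must fall after the last lap start")
    edges = np.concatenate([starts, [float(session_end_s)]])
    return [(float(edges[i]), float(edges[i + 1]), states[i]) for i in range(len(starts))]


def label_windows(
    timeline: LapTimeline,
    grid: WindowGrid,
    session_end_s: Optional[float] = None,
    transition_buffer_s: Optional[float] = None,
) -> list[Optional[str]]:
    """Comfort label per window by majority overlap with the lap timeline.

    A window spanning a transition takes the state occupying the majority
    of its 60 s; an exact tie takes the state at the window start. With
    ``transition_buffer_s`` set, any window whose span comes within that
    buffer of a lap boundary is labelled None (excluded), quantifying
    sensitivity to label-edge noise near gradual comfort transitions.
    """
    if session_end_s is None:
        session_end_s = float(grid.starts[-1] + grid.window_s)
    # laps may nominally start after a gap-truncated usable span; extending the
    # end past every boundary keeps the interval arithmetic well-defined there
    all_starts, _ = timeline.effective_boundaries()
    end = max(session_end_s, grid.starts[-1] + grid.window_s, all_starts[-1] + 1e-6)
    intervals = state_intervals(timeline, end)
    boundaries = [iv[0] for iv in intervals[1:]]
    labels: list[Optional[str]] = []
    for w0, w1 in grid.intervals():
        if transition_buffer_s is not None and any(
            w0 - transition_buffer_s < b < w1 + transition_buffer_s for b in boundaries
        ):
            labels.append(None)
            continue
        overlap: dict[str, float] = {}
        start_state = None
        for s0, s1, state in intervals:
            if s0 <= w0 < s1:
                start_state = state
            ov = min(w1, s1) - max(w0, s0)
            if ov > 0:
                overlap[state] = overlap.get(state, 0.0) + ov
        if not overlap:
            labels.append(None)
            continue
        best = max(overlap.values())
        winners = [st for st, ov in overlap.items() if ov == best]
        if len(winners) == 1:
            labels.append(winners[0])
        else:
            labels.append(start_state if start_state in winners else winners[0])
    return labels
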