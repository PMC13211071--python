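"""End-to-end session processing: raw bundle → labelled feature rows.

Per session: resolve the watch's local-time strings to an elapsed axis,
find the sync gesture on both accelerometers (or take manual anchors),
shift phone times onto the watch clock, gate on data-loss gaps, trim the
usable window, build the 60 s grid, label it from the lap timeline, and
extract the HRV and context feature blocks. Cohort level: assemble the
unified matrix and apply the normalisation policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import context as ctx
from . import hrv, sync
from .features import FeatureSchema, assemble, normalise
from .streams import (
    LapTimeline,
    SessionBundle,
    read_session_dir,
    resolve_local_times,
    unpack_packed_accel,
)

OPTIONS_FILE = "options.yaml"


@dataclass
class SessionOptions:
    """Per-session manual corrections and tuning.

    Manual sync anchors take precedence over the automatic spike detector;
    lap overrides and inserted boundaries correct missed lap presses.
    """

    manual_anchors: Optional[sync.SyncAnchors] = None
    lap_overrides: dict[int, str] = field(default_factory=dict)
    insert_boundaries: list[float] = field(default_factory=list)
    transition_buffer_s: Optional[float] = None
    gap_threshold_s: float = sync.DEFAULT_GAP_THRESHOLD_S
    pad_s: float = sync.DEFAULT_PAD_S
    hr_params: ctx.HrReserveParams = field(default_factory=ctx.HrReserveParams)
    audit: bool = False

    @classmethod
    def from_yaml(cls, path) -> "SessionOptions":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        anchors = None
        if "sync" in raw:
            anchors = sync.SyncAnchors(
                t_garmin_sync=float(raw["sync"]["garmin_s"]),
                t_oppo_sync=float(raw["sync"]["oppo_s"]),
                source="manual",
            )
        return cls(
            manual_anchors=anchors,
            lap_overrides={int(k): v for k, v in raw.get("lap_overrides", {}).items()},
            insert_boundaries=[float(b) for b in raw.get("insert_boundaries", [])],
            transition_buffer_s=raw.get("transition_buffer_s"),
        )


@dataclass
class SessionFeatures:
    """One processed session: per-window feature blocks plus provenance."""

    session_id: str
    anchors: sync.SyncAnchors
    usable: sync.UsableWindow
    grid: sync.WindowGrid
    labels: list[Optional[str]]
    hrv_rows: dict[int, dict[str, float]]
    context_rows: dict[int, dict[str, float]]


def record_elapsed_seconds(bundle: SessionBundle) -> np.ndarray:
    """Watch record timestamps as elapsed seconds from the session start,
    midnight-safe via the local-time resolution guard."""
    absolute = resolve_local_times(bundle.records, bundle.meta)
    return (absolute - absolute[0]).total_seconds().to_numpy()


def wrist_accel_magnitude(
    bundle: SessionBundle, record_times: np.ndarray, up_to_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unpacked 25 Hz wrist accelerometer magnitudes up to ``up_to_s``."""
    times, mags = [], []
    packed = bundle.records.data["packed_accel"].to_numpy()
    for i in range(len(record_times)):
        if record_times[i] > up_to_s:
            break
        t, v = unpack_packed_accel(record_times[i], packed[i])
        times.append(t)
        mags.append(v)
    return np.concatenate(times), np.concatenate(mags)


def detect_anchors(
    bundle: SessionBundle,
    record_times: np.ndarray,
    search_window_s: float = 20.0,
) -> sync.SyncAnchors:
    """Automatic sync anchors from the gesture spike on both devices.

    Advisory: a low-confidence detection on either stream raises
    :class:`sync.NoSyncDetectedError` so the session is flagged for manual
    anchor entry rather than silently misaligned.
    """
    phone_det = sync.detect_sync_spike(
        bundle.phone.t_elapsed, bundle.phone.accel_magnitude(), search_window_s
    )
    wt, wm = wrist_accel_magnitude(bundle, record_times, search_window_s + 5)
    watch_det = sync.detect_sync_spike(wt, wm, search_window_s)
    if not (phone_det.confident and watch_det.confident):
        raise sync.NoSyncDetectedError(
            "ambiguous sync gesture; enter manual anchors"
        )
    return sync.SyncAnchors(
        t_garmin_sync=watch_det.time_s,
        t_oppo_sync=phone_det.time_s,
        source="detected",
    )


def process_bundle(
    bundle: SessionBundle, options: SessionOptions | None = None
) -> SessionFeatures:
    """Run one session through alignment, windowing and feature extraction."""
    options = options or SessionOptions()
    record_times = record_elapsed_seconds(bundle)
    anchors = options.manual_anchors or detect_anchors(bundle, record_times)

    phone_aligned = sync.align_clocks(anchors, bundle.phone.t_elapsed)
    gap_phone = sync.detect_gap(bundle.phone, options.gap_threshold_s)
    gap_aligned = None if gap_phone is None else gap_phone + anchors.offset_s
    usable = sync.compute_usable_window(
        phone_end_s=float(phone_aligned[-1]),
        record_end_s=float(record_times[-1]),
        gap_time_s=gap_aligned,
        pad_s=options.pad_s,
    )
    grid = sync.build_window_grid(usable)

    laps = bundle.laps
    if options.lap_overrides or options.insert_boundaries:
        laps = LapTimeline(
            lap_starts=laps.lap_starts,
            overrides=dict(options.lap_overrides),
            inserted_boundaries=list(options.insert_boundaries),
        )
    labels = sync.label_windows(
        laps, grid,
        session_end_s=usable.end_s + options.pad_s,
        transition_buffer_s=options.transition_buffer_s,
    )

    rr_clean, _ = hrv.reject_artifacts(bundle.rr)
    beats = hrv.reconstruct_beat_times(rr_clean, usable.start_s)
    hrv_rows = hrv.extract_hrv_windows(beats, grid)
    context_rows = ctx.extract_context_windows(
        bundle.phone, bundle.records, grid,
        phone_aligned_times=phone_aligned,
        record_times=record_times,
        params=options.hr_params,
        audit=options.audit,
    )
    return SessionFeatures(
        session_id=bundle.session_id,
        anchors=anchors,
        usable=usable,
        grid=grid,
        labels=labels,
        hrv_rows=hrv_rows,
        context_rows=context_rows,
    )


def build_feature_matrix(
    processed: list[SessionFeatures],
    schema: FeatureSchema | None = None,
    normalised: bool = True,
) -> pd.DataFrame:
    """Assemble processed sessions into the modelled feature matrix."""
    schema = schema or FeatureSchema.default()
    hrv_rows: dict[tuple[str, int], dict[str, float]] = {}
    context_rows: dict[tuple[str, int], dict[str, float]] = {}
    labels: dict[tuple[str, int], str] = {}
    starts: dict[tuple[str, int], float] = {}
    for sf in processed:
        for idx, row in sf.hrv_rows.items():
            hrv_rows[(sf.session_id, idx)] = row
        for idx, row in sf.context_rows.items():
            context_rows[(sf.session_id, idx)] = row
        for idx, label in enumerate(sf.labels):
            if label is not None:
                labels[(sf.session_id, idx)] = label
                starts[(sf.session_id, idx)] = float(sf.grid.starts[idx])
    matrix = assemble(hrv_rows, context_rows, labels, starts, schema)
    return normalise(matrix, schema) if normalised else matrix


def process_session_dir(path, options: SessionOptions | None = None) -> SessionFeatures:
    """Load and process one on-disk session directory; picks up
    ``options.yaml`` (manual anchors, lap corrections) when present."""
    path = Path(path)
    if options is None and (path / OPTIONS_FILE).exists():
        options = SessionOptions.from_yaml(path / OPTIONS_FILE)
    return process_bundle(read_session_dir(path), options)


def process_cohort(
    bundles: list[SessionBundle],
    options: dict[str, SessionOptions] | None = None,
    normalised: bool = True,
) -> pd.DataFrame:
    """Process in-memory bundles into a normalised feature matrix."""
    processed = [
        process_bundle(b, (options or {}).get(b.session_id)) for b in bundles
    ]
    return build_feature_matrix(processed, normalised=normalised)
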