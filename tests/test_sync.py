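"""Gap gating, clock alignment, spike detection, lap logic, window labels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from comfortfuse.streams import COMFORTABLE, UNCOMFORTABLE, LapTimeline, PhoneStream
from comfortfuse.sync import (
    NoSyncDetectedError,
    SessionTooShortError,
    SyncAnchors,
    UsableWindow,
    WindowGrid,
    align_clocks,
    build_window_grid,
    compute_usable_window,
    detect_gap,
    detect_sync_spike,
    label_windows,
    lap_durations,
)


def _phone(t):
    t = np.asarray(t, dtype=float)
    n = len(t)
    cols = {c: np.zeros(n) for c in
            ["ax", "ay", "az", "gyro_x", "gyro_y", "gyro_z",
             "grav_x", "grav_y", "grav_z", "mag_x", "mag_y", "mag_z",
             "sound", "lux"]}
    return PhoneStream(pd.DataFrame({"t_elapsed": t, **cols}))


class TestDetectGap:
    def test_regular_spacing_has_no_gap(self):
        assert detect_gap(_phone(np.arange(0, 60, 0.1))) is None

    def test_returns_last_good_sample_before_gap(self):
        t = np.concatenate([np.arange(0, 100.1, 0.1), np.arange(110.2, 120, 0.1)])
        assert detect_gap(_phone(t)) == pytest.approx(100.0)

    def test_first_of_two_gaps_wins(self):
        t = np.concatenate([
            np.arange(0, 50.1, 0.1),       # gap of 6 s at t=50
            np.arange(56.1, 90.1, 0.1),    # gap of 8 s at t=90
            np.arange(98.1, 110, 0.1),
        ])
        assert detect_gap(_phone(t)) == pytest.approx(50.0)


class TestAlignClocks:
    def test_anchor_maps_to_anchor(self):
        anchors = SyncAnchors(t_garmin_sync=12.0, t_oppo_sync=9.0)
        assert align_clocks(anchors, np.array([9.0]))[0] == pytest.approx(12.0)

    def test_equal_anchors_are_identity(self):
        anchors = SyncAnchors(5.0, 5.0)
        t = np.linspace(0, 100, 11)
        np.testing.assert_allclose(align_clocks(anchors, t), t)

    def test_swapped_anchors_invert_exactly(self, rng):
        t = rng.uniform(0, 1000, 100)
        fwd = SyncAnchors(t_garmin_sync=37.25, t_oppo_sync=33.5)
        back = SyncAnchors(t_garmin_sync=33.5, t_oppo_sync=37.25)
        np.testing.assert_allclose(
            align_clocks(back, align_clocks(fwd, t)), t, rtol=0, atol=1e-9
        )


class TestDetectSyncSpike:
    def test_last_swing_of_clean_triple_spike(self, rng):
        t = np.arange(0, 20, 0.1)
        m = np.abs(rng.normal(0.3, 0.1, len(t)))
        for swing in (4.0, 5.0, 6.0):
            m[np.argmin(np.abs(t - swing))] = 15.0
        det = detect_sync_spike(t, m)
        assert det.time_s == pytest.approx(6.0)
        assert det.confident

    def test_flat_stream_raises(self):
        t = np.arange(0, 25, 0.1)
        with pytest.raises(NoSyncDetectedError):
            detect_sync_spike(t, np.full(len(t), 0.5))

    def test_offset_recovered_across_cohort_within_tolerance(self):
        """Detected watch-minus-phone anchor difference recovers the true
        clock offset to within 0.2 s on every clean-spike session."""
        from comfortfuse.pipeline import detect_anchors, record_elapsed_seconds
        from comfortfuse.synth import SynthConfig, generate_cohort

        config = SynthConfig(
            n_sessions=8, session_duration_s=600.0, clock_offset_s=2.7, seed=21
        )
        for bundle, truth in generate_cohort(config):
            rt = record_elapsed_seconds(bundle)
            anchors = detect_anchors(bundle, rt)
            assert anchors.source == "detected"
            assert abs(anchors.offset_s - truth.true_offset_s) < 0.2


class TestUsableWindow:
    def test_gap_free_session_pads_both_ends(self):
        w = compute_usable_window(600.0, 600.0)
        assert (w.start_s, w.end_s) == (90.0, 510.0)
        assert w.duration_s == 420.0

    def test_gap_session_has_start_padding_only(self):
        w = compute_usable_window(600.0, 600.0, gap_time_s=400.0)
        assert (w.start_s, w.end_s) == (90.0, 400.0)
        assert w.gap_detected

    def test_short_session_rejected(self):
        with pytest.raises(SessionTooShortError):
            compute_usable_window(150.0, 150.0)

    def test_end_is_earlier_device(self):
        assert compute_usable_window(800.0, 600.0).end_s == 510.0

    def test_window_count_matches_usable_duration(self):
        for dur in (600.0, 610.0, 659.9, 660.0, 1500.0):
            usable = compute_usable_window(dur, dur)
            grid = build_window_grid(usable)
            assert len(grid) == int(np.floor(usable.duration_s / 60.0))


class TestLapDurations:
    def test_consecutive_start_differences(self):
        tl = LapTimeline(np.array([0.0, 120.0, 300.0]))
        np.testing.assert_allclose(lap_durations(tl, 420.0), [120.0, 180.0, 120.0])

    def test_single_lap_runs_to_session_end(self):
        np.testing.assert_allclose(lap_durations(LapTimeline([0.0]), 600.0), [600.0])

    def test_zero_length_final_lap_rejected(self):
        with pytest.raises(ValueError):
            lap_durations(LapTimeline(np.array([0.0, 100.0])), 100.0)

    def test_durations_conserve_total(self):
        tl = LapTimeline(np.array([0.0, 77.0, 191.0, 402.0]))
        assert lap_durations(tl, 900.0).sum() == pytest.approx(900.0)


class TestLabelWindows:
    def test_parity_labelling(self):
        tl = LapTimeline(np.array([0.0, 300.0]))
        grid = WindowGrid(np.arange(0.0, 420.0, 60.0))
        labels = label_windows(tl, grid, session_end_s=420.0)
        assert labels == [COMFORTABLE] * 5 + [UNCOMFORTABLE] * 2

    def test_lap_zero_override_flips_first_block(self):
        tl = LapTimeline(np.array([0.0, 300.0]), overrides={0: UNCOMFORTABLE})
        grid = WindowGrid(np.arange(0.0, 420.0, 60.0))
        labels = label_windows(tl, grid, session_end_s=420.0)
        assert labels == [UNCOMFORTABLE] * 7

    def test_tie_breaks_to_window_start_state(self):
        tl = LapTimeline(np.array([0.0, 300.0]))
        grid = WindowGrid(np.array([270.0]))
        # [270, 330) overlaps 30 s of each state; the window starts comfortable
        assert label_windows(tl, grid, session_end_s=600.0) == [COMFORTABLE]

    def test_majority_overlap_wins(self):
        tl = LapTimeline(np.array([0.0, 290.0]))
        grid = WindowGrid(np.array([270.0]))  # 20 s comfortable vs 40 s not
        assert label_windows(tl, grid, session_end_s=600.0) == [UNCOMFORTABLE]

    def test_inserted_boundary_splits_a_lap(self):
        tl = LapTimeline(np.array([0.0]), inserted_boundaries=[120.0])
        grid = WindowGrid(np.array([0.0, 60.0, 120.0, 180.0]))
        labels = label_windows(tl, grid, session_end_s=240.0)
        assert labels == [COMFORTABLE, COMFORTABLE, UNCOMFORTABLE, UNCOMFORTABLE]

    def test_transition_buffer_excludes_boundary_windows(self):
        tl = LapTimeline(np.array([0.0, 300.0]))
        grid = WindowGrid(np.arange(0.0, 420.0, 60.0))
        labels = label_windows(
            tl, grid, session_end_s=420.0, transition_buffer_s=30.0
        )
        # windows [240,300) and [300,360) sit within 30 s of the boundary
        assert labels[4] is None and labels[5] is None
        assert labels[:4] == [COMFORTABLE] * 4 and labels[6] == UNCOMFORTABLE
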