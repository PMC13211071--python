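"""HRV features against hand computations and brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from comfortfuse.hrv import (
    BeatSeries,
    EmptySeriesError,
    extract_hrv_windows,
    lomb_scargle_psd,
    poincare,
    reconstruct_beat_times,
    reject_artifacts,
    sample_entropy,
    spectral_power,
    time_domain,
)
from comfortfuse.sync import WindowGrid


# ---------------------------------------------------------------------------
# independent oracles

def sampen_bruteforce(x, m=2, r_factor=0.2):
    """Direct O(n²) pairwise template counting, plain Python loops."""
    x = list(map(float, x))
    n = len(x)
    sd = np.std(x, ddof=1)
    if sd == 0:
        return float("nan")
    r = r_factor * sd

    def count(length):
        total = 0
        for i in range(n - length + 1):
            for j in range(i + 1, n - length + 1):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    total += 1
        return total

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def poincare_rotated_oracle(rr):
    """SD1/SD2 from the lag-1 scatter rotated 45°: dispersion perpendicular
    and parallel to the identity line."""
    rr = np.asarray(rr, dtype=float)
    x, y = rr[:-1], rr[1:]
    perp = (x - y) / np.sqrt(2)
    return float(np.std(perp, ddof=1))


# ---------------------------------------------------------------------------
# artifact rejection and beat-time reconstruction

class TestArtifacts:
    def test_out_of_band_intervals_removed(self):
        kept, mask = reject_artifacts(np.array([1000.0, 200.0, 1600.0, 800.0]))
        np.testing.assert_array_equal(kept, [1000.0, 800.0])
        np.testing.assert_array_equal(mask, [True, False, False, True])

    def test_in_band_series_untouched(self, rng):
        rr = rng.uniform(400, 1400, 200)
        kept, mask = reject_artifacts(rr)
        assert mask.all()
        np.testing.assert_array_equal(kept, rr)

    def test_band_edges_are_inclusive(self):
        kept, _ = reject_artifacts(np.array([333.0, 1500.0, 332.9, 1500.1]))
        np.testing.assert_array_equal(kept, [333.0, 1500.0])

    def test_fully_rejected_stream_signals_empty(self):
        with pytest.raises(EmptySeriesError):
            reject_artifacts(np.array([100.0, 2000.0]))


class TestBeatTimes:
    def test_first_beat_anchored_and_cumulative(self):
        beats = reconstruct_beat_times(np.array([1000.0, 500.0]), 0.0)
        np.testing.assert_allclose(beats.beat_time, [0.0, 0.5])

    def test_start_offset_shifts_all_times(self):
        rr = np.array([800.0, 820.0, 790.0])
        a = reconstruct_beat_times(rr, 0.0)
        b = reconstruct_beat_times(rr, 90.0)
        np.testing.assert_allclose(b.beat_time, a.beat_time + 90.0)

    def test_round_trip_diffs_recover_intervals(self, rng):
        rr = rng.uniform(600, 1100, 80)
        beats = reconstruct_beat_times(rr, 90.0)
        np.testing.assert_allclose(np.diff(beats.beat_time) * 1000.0, rr[1:])


# ---------------------------------------------------------------------------
# time domain

class TestTimeDomain:
    def test_constant_series_is_degenerate(self):
        f = time_domain(np.full(60, 1000.0))
        assert f["sdnn"] == 0 and f["rmssd"] == 0 and f["pnn50"] == 0
        assert f["mean_hr"] == pytest.approx(60.0)

    def test_hand_computed_three_beat_example(self):
        f = time_domain(np.array([1000.0, 1050.0, 1000.0]))
        assert f["rmssd"] == pytest.approx(50.0)
        assert f["sdsd"] == pytest.approx(70.710678, abs=1e-6)
        assert f["pnn50"] == 0.0

    def test_alternating_large_differences_saturate_pnn50(self):
        f = time_domain(np.array([800.0, 900.0, 800.0, 900.0]))
        assert f["pnn50"] == 100.0

    def test_rmssd_sdsd_relation_for_zero_mean_diffs(self, rng):
        # construct a series whose successive differences sum to zero
        diffs = rng.normal(0, 30, 59)
        diffs -= diffs.mean()
        rr = 900.0 + np.concatenate([[0.0], np.cumsum(diffs)])
        f = time_domain(rr)
        n = len(diffs)
        assert f["rmssd"] == pytest.approx(f["sdsd"] * np.sqrt((n - 1) / n), rel=1e-9)


# ---------------------------------------------------------------------------
# spectral

def _modulated_beats(mod_hz, n_s=300, mean_ms=800.0, depth_ms=40.0, seed=0):
    rng = np.random.default_rng(seed)
    t, rr = 0.0, []
    while t < n_s:
        v = mean_ms + depth_ms * np.sin(2 * np.pi * mod_hz * t) + rng.normal(0, 3)
        rr.append(v)
        t += v / 1000.0
    return reconstruct_beat_times(np.array(rr), 0.0)


class TestSpectral:
    def test_hf_tone_lands_in_hf_band(self):
        p = spectral_power(_modulated_beats(0.25))
        assert p["hf_power"] / p["total_power"] > 0.9

    def test_lf_tone_lands_in_lf_band(self):
        p = spectral_power(_modulated_beats(0.10))
        assert p["lf_power"] / p["total_power"] > 0.9

    def test_white_noise_ratio_finite_positive(self, rng):
        rr = rng.normal(850, 40, 120)
        beats = reconstruct_beat_times(rr, 0.0)
        p = spectral_power(beats)
        assert np.isfinite(p["lf_hf_ratio"]) and p["lf_hf_ratio"] > 0

    def test_band_power_invariant_under_time_shift(self, rng):
        rr = rng.normal(850, 40, 100)
        a = spectral_power(reconstruct_beat_times(rr, 0.0))
        b = spectral_power(reconstruct_beat_times(rr, 1234.5))
        for key in ("lf_power", "hf_power", "total_power"):
            assert a[key] == pytest.approx(b[key], rel=1e-9)

    def test_powers_are_nonnegative(self, rng):
        for seed in range(5):
            rr = np.random.default_rng(seed).normal(800, 50, 90)
            p = spectral_power(reconstruct_beat_times(rr, 0.0))
            assert p["lf_power"] >= 0 and p["hf_power"] >= 0


# ---------------------------------------------------------------------------
# nonlinear

class TestPoincare:
    def test_constant_series_collapses(self):
        f = poincare(np.full(30, 1000.0))
        assert f["sd1"] == 0 and f["sd2"] == 0
        assert math.isnan(f["sd1_sd2_ratio"])

    def test_hand_computed_sd1(self):
        f = poincare(np.array([1000.0, 1050.0, 1000.0]))
        assert f["sd1"] == pytest.approx(50.0)

    def test_sd1_matches_rotated_scatter_oracle(self, rng):
        for _ in range(5):
            rr = rng.normal(850, 45, 70)
            f = poincare(rr)
            assert f["sd1"] == pytest.approx(poincare_rotated_oracle(rr), abs=1e-9)

    def test_ratio_consistency(self, rng):
        rr = rng.normal(850, 45, 70)
        f = poincare(rr)
        assert f["sd1_sd2_ratio"] == pytest.approx(f["sd1"] / f["sd2"], rel=1e-12)


class TestSampleEntropy:
    def test_constant_series_is_missing(self):
        assert math.isnan(sample_entropy(np.full(40, 900.0)))

    def test_periodic_series_near_zero_and_matches_oracle(self):
        rr = np.array([800.0, 1000.0] * 30)
        got = sample_entropy(rr)
        expect = sampen_bruteforce(rr)
        assert got == pytest.approx(expect, abs=1e-12)
        assert got < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_on_random_series(self, seed):
        rr = np.random.default_rng(seed).normal(850, 40, 60)
        got = sample_entropy(rr)
        expect = sampen_bruteforce(rr)
        if math.isnan(expect):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expect, abs=1e-12)


# ---------------------------------------------------------------------------
# windowing

class TestWindowExtraction:
    def test_sixty_second_window_of_second_beats_emits_row(self):
        beats = reconstruct_beat_times(np.full(60, 1000.0), 0.0)
        rows = extract_hrv_windows(beats, WindowGrid(np.array([0.0])))
        assert 0 in rows
        assert rows[0]["n_beats"] == 60

    def test_sparse_window_discarded(self):
        beats = reconstruct_beat_times(np.full(25, 1450.0), 0.0)
        rows = extract_hrv_windows(beats, WindowGrid(np.array([0.0])))
        assert rows == {}

    def test_boundary_beat_belongs_to_next_window(self):
        # 61 beats at 1 s spacing: beat 60 sits exactly at t=60
        beats = reconstruct_beat_times(np.full(61, 1000.0), 0.0)
        rows = extract_hrv_windows(beats, WindowGrid(np.array([0.0, 60.0])))
        assert rows[0]["n_beats"] == 60
        in_second = (beats.beat_time >= 60.0).sum()
        assert in_second == 1
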