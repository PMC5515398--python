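"""Behavioural quantification: events, lengths, bouts, tracking."""

import numpy as np
import pytest

from virtualrig import behav, fluo
from virtualrig.behav import (
    contraction_metrics,
    detect_events,
    fin_bout_detect,
    larval_length_series,
    track_centroids,
)
from virtualrig.stackio import DiskROI, ImageStack, Trace
from virtualrig.synthcam import CameraConfig, simulate_per_fly, simulate_tethered_fish


def square_wave_trace(on_s=1.0, off_s=2.0, repeats=5, rate=42.0, amp=100.0) -> Trace:
    duration = repeats * (on_s + off_s)
    t = np.arange(0, duration, 1 / rate)
    phase = t % (on_s + off_s)
    return Trace(times_s=t, values=np.where(phase < on_s, amp, 0.0))


class TestDetectEvents:
    def test_square_wave_five_events_three_seconds_apart(self):
        events = detect_events(square_wave_trace(), threshold=50.0)
        assert len(events) == 5
        assert np.allclose(np.diff(events.onsets_s), 3.0, atol=0.05)

    def test_constant_trace_empty(self):
        trace = Trace(times_s=np.arange(10.0), values=np.full(10, 3.3))
        assert len(detect_events(trace)) == 0

    def test_short_gaps_merged(self):
        t = np.arange(0, 1, 0.01)
        v = np.zeros_like(t)
        v[(t >= 0.2) & (t < 0.4)] = 10
        v[(t >= 0.45) & (t < 0.6)] = 10  # 50 ms gap
        events = detect_events(Trace(times_s=t, values=v), threshold=5.0, min_gap_s=0.1)
        assert len(events) == 1
        assert events.intervals[0] == pytest.approx((0.2, 0.6), abs=0.02)

    def test_min_duration_drops_blips(self):
        t = np.arange(0, 1, 0.01)
        v = np.zeros_like(t)
        v[50:53] = 10  # 30 ms blip
        events = detect_events(Trace(times_s=t, values=v), threshold=5.0, min_duration_s=0.1)
        assert len(events) == 0

    def test_idempotent_on_own_reconstruction(self):
        trace = square_wave_trace()
        events = detect_events(trace, threshold=50.0)
        rebuilt = np.zeros_like(trace.values)
        for a, b in events.intervals:
            rebuilt[(trace.times_s >= a) & (trace.times_s < b)] = 100.0
        again = detect_events(Trace(times_s=trace.times_s, values=rebuilt), threshold=50.0)
        assert again.intervals == pytest.approx(events.intervals)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_events(Trace(times_s=np.array([]), values=np.array([])))


def rod_stack(length_px=120, thickness=9, pixel_um=50.0) -> ImageStack:
    frame = np.zeros((60, 160), dtype=np.uint8)
    y0 = 30 - thickness // 2
    frame[y0 : y0 + thickness, 20 : 20 + length_px] = 255
    return ImageStack(frames=frame[None], pixel_size_um=pixel_um)


def arc_stack(radius_px=50, thickness=9, pixel_um=50.0) -> ImageStack:
    h, w = 90, 140
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = 75.0, 70.0
    r = np.hypot(yy - cy, xx - cx)
    mask = (np.abs(r - radius_px) <= thickness / 2) & (yy <= cy)  # upper semicircle
    return ImageStack(frames=(mask * 255).astype(np.uint8)[None], pixel_size_um=pixel_um)


class TestLarvalLength:
    def test_straight_rod_within_five_percent(self):
        stack = rod_stack()
        trace = larval_length_series(stack, intensity_polarity="light_on_dark")
        assert trace.units == "mm"
        assert trace.values[0] == pytest.approx(120 * 50.0 / 1000, rel=0.05)

    def test_semicircular_arc_geodesic_not_chord(self):
        radius = 50
        trace = larval_length_series(arc_stack(radius), intensity_polarity="light_on_dark")
        expected_mm = np.pi * radius * 50.0 / 1000
        assert trace.values[0] == pytest.approx(expected_mm, rel=0.05)
        # a chord/major-axis measure would see only the 2r diameter
        assert trace.values[0] > 2.5 * radius * 50.0 / 1000

    def test_rigid_translation_constant_within_two_percent(self):
        base = rod_stack().frames[0]
        frames = np.stack([np.roll(base, (dy, 2 * dy), axis=(0, 1)) for dy in range(5)])
        stack = ImageStack(frames=frames, pixel_size_um=50.0)
        trace = larval_length_series(stack, intensity_polarity="light_on_dark")
        assert np.ptp(trace.values) / trace.values.mean() < 0.02

    def test_blank_frame_rejected(self):
        with pytest.raises(ValueError, match="no component"):
            larval_length_series(ImageStack(frames=np.zeros((1, 8, 8), dtype=np.uint8)))


class TestContractionMetrics:
    def test_constant_length(self):
        t = np.arange(0, 10, 0.1)
        lengths = Trace(times_s=t, values=np.full_like(t, 4.0), units="mm")
        s = contraction_metrics(lengths, flash_onset_s=2.0)
        assert s.contraction == 0.0 and s.recovery == 1.0

    def test_twenty_percent_contraction_recovers(self):
        t = np.arange(0, 10, 0.02)
        v = np.full_like(t, 4.0)
        v[(t >= 2.0) & (t < 4.0)] = 3.2  # 20% shorter during/after the flash
        s = contraction_metrics(Trace(times_s=t, values=v, units="mm"), flash_onset_s=2.0)
        assert s.contraction == pytest.approx(0.20, abs=0.01)
        assert s.recovery == pytest.approx(1.0, abs=0.01)

    def test_flash_at_trace_end_rejected(self):
        t = np.arange(0, 3, 0.1)
        lengths = Trace(times_s=t, values=np.full_like(t, 4.0), units="mm")
        with pytest.raises(ValueError, match="out of range"):
            contraction_metrics(lengths, flash_onset_s=2.9)


def small_cam(**kw):
    defaults = dict(full_width=128, full_height=96, binning=1, frame_rate_hz=42.0,
                    pixel_size_um=10.0, photon_scale=1000.0)
    defaults.update(kw)
    return CameraConfig(**defaults)


class TestPer:
    def test_event_count_and_onsets_across_seeds(self):
        for seed in range(10):
            stack, truth = simulate_per_fly(cam=small_cam(), seed=seed)
            roi = DiskROI(**truth.payload["tip_roi"])
            _, events = behav.analyze_per(stack, roi)
            truth_onsets = [a for a, _ in truth.payload["extension_intervals"]]
            assert len(events) == len(truth_onsets)
            dt = 1 / stack.frame_rate_hz
            assert np.max(np.abs(np.array(events.onsets_s) - truth_onsets)) <= 2 * dt

    def test_artefact_only_control_is_flat_after_subtraction(self):
        stack, truth = simulate_per_fly(cam=small_cam(), seed=3, extension_enabled=False)
        roi = DiskROI(**truth.payload["tip_roi"])
        trace, events = behav.analyze_per(stack, roi, threshold=10.0)
        assert len(events) == 0
        assert np.ptp(trace.values) < 10.0  # well below the 0.45-peak extension signal

    def test_per_trace_requires_grayscale(self):
        stack, truth = simulate_per_fly(cam=small_cam(), seed=0)
        with pytest.raises(ValueError):
            behav.per_trace(stack, DiskROI(**truth.payload["tip_roi"]))


class TestFinBouts:
    @staticmethod
    def fin_traces(stack, truth):
        from virtualrig.stackio import to_grayscale

        gray = to_grayscale(stack)
        left = fluo.roi_trace(gray, DiskROI(**truth.payload["left_fin_roi"]))
        right = fluo.roi_trace(gray, DiskROI(**truth.payload["right_fin_roi"]))
        return left, right

    def test_verdicts_follow_duration_threshold(self):
        stimuli = [(1.0, 0.6), (4.0, 0.15)]
        stack, truth = simulate_tethered_fish(cam=small_cam(), stimuli=stimuli, seed=1)
        left, right = self.fin_traces(stack, truth)
        verdicts = fin_bout_detect(left, right, stimuli)
        assert [v.bout for v in verdicts] == [True, False]

    def test_latency_matches_generator_within_one_frame(self):
        stimuli = [(1.0, 0.6)]
        stack, truth = simulate_tethered_fish(cam=small_cam(), stimuli=stimuli, seed=2)
        left, right = self.fin_traces(stack, truth)
        v = fin_bout_detect(left, right, stimuli)[0]
        assert v.latency_s == pytest.approx(truth.payload["latency_s"],
                                            abs=1.5 / stack.frame_rate_hz)

    def test_no_stimuli_empty_verdicts(self):
        stack, truth = simulate_tethered_fish(cam=small_cam(), stimuli=[(1.0, 0.6)], seed=0)
        left, right = self.fin_traces(stack, truth)
        assert fin_bout_detect(left, right, []) == []

    def test_overlapping_windows_rejected(self):
        stack, truth = simulate_tethered_fish(cam=small_cam(), stimuli=[(1.0, 0.6)], seed=0)
        left, right = self.fin_traces(stack, truth)
        with pytest.raises(ValueError, match="overlap"):
            fin_bout_detect(left, right, [(1.0, 0.2), (1.5, 0.2)], response_window_s=1.0)


def moving_blob_stack(n_frames=20, step=2, start=(10, 20)) -> ImageStack:
    frames = np.full((n_frames, 60, 80), 200, dtype=np.uint8)
    for i in range(n_frames):
        cy, cx = start[0] + 0 * i, start[1] + step * i
        frames[i, cy - 3 : cy + 4, cx - 3 : cx + 4] = 20
    return ImageStack(frames=frames, frame_rate_hz=15.0)


class TestTracker:
    def test_single_blob_matches_truth(self):
        tracks = track_centroids(moving_blob_stack())
        assert len(tracks) == 1
        xs = [c[0] for c in tracks[0].centroids]
        assert np.allclose(np.diff(xs), 2.0, atol=0.1)
        assert len(tracks[0]) == 20

    def test_jump_beyond_max_starts_new_track(self):
        frames = np.full((10, 60, 80), 200, dtype=np.uint8)
        for i in range(10):
            cx = 20 if i < 5 else 60  # 40 px teleport at frame 5
            frames[i, 27:34, cx - 3 : cx + 4] = 20
        tracks = track_centroids(ImageStack(frames=frames), max_jump_px=15.0)
        assert len(tracks) == 2
        assert len(tracks[0]) == 5 and len(tracks[1]) == 5

    def test_empty_video_empty_tracks(self):
        stack = ImageStack(frames=np.full((5, 20, 20), 200, dtype=np.uint8))
        assert track_centroids(stack) == []

    def test_five_flies_perfect_recall_no_switches(self):
        from virtualrig.synthcam import simulate_arena_flies

        stack, truth = simulate_arena_flies(seed=8, duration_s=8.0)
        tracks = track_centroids(stack, max_jump_px=12.0)
        tracks = [t for t in tracks if len(t) > 2]
        assert len(tracks) == 5
        true_tracks = np.asarray(truth.payload["tracks_px"])  # (5, T, 2)
        for track in tracks:
            assert len(track) == stack.n_frames  # full-length: recall 1.0, no splits
            est = np.asarray(track.centroids)
            idx = np.asarray(track.frame_indices)
            # nearest true identity per frame must be constant: zero switches
            d = np.linalg.norm(true_tracks[:, idx, :] - est[None], axis=2)
            assigned = np.argmin(d, axis=0)
            assert np.all(assigned == assigned[0])
            assert d[assigned[0], np.arange(len(idx))].max() < 2.0  # precision: sub-blob error
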