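"""Synthetic-scene generators: determinism, noise model, ground-truth contracts."""

import numpy as np
import pytest

from virtualrig import rig
from virtualrig.synthcam import (
    CameraConfig,
    LarvaSceneConfig,
    simulate_arena_flies,
    simulate_beads,
    simulate_crawling_larva,
    simulate_per_fly,
    simulate_tethered_fish,
)
from virtualrig.stackio import DiskROI, extract_channel
from virtualrig import fluo


def small_cam(**kw):
    defaults = dict(full_width=128, full_height=96, binning=1, frame_rate_hz=42.0,
                    pixel_size_um=10.0, photon_scale=1000.0)
    defaults.update(kw)
    return CameraConfig(**defaults)


class TestCameraConfig:
    def test_binning_rate_pairing(self):
        assert CameraConfig(binning=1).rate_hz == 15
        assert CameraConfig(binning=2).rate_hz == 42
        assert CameraConfig(binning=4).rate_hz == 90

    def test_binned_geometry(self):
        cam = CameraConfig(binning=2)
        assert (cam.out_width, cam.out_height) == (1296, 972)
        assert cam.out_pixel_size_um == 2.0

    def test_invalid_binning(self):
        with pytest.raises(ValueError):
            CameraConfig(binning=3)


class TestNoiseModel:
    def test_mean_and_variance_of_flat_field(self):
        cam = CameraConfig(full_width=256, full_height=256, binning=1,
                           photon_scale=400.0, read_noise_sd=1.0)
        # a "bead field" with zero beads is a flat field at the background level
        stack, _ = simulate_beads(cam=cam, n_beads=0, sigma_um=2.0, seed=7, background=0.3)
        grey = stack.frames.astype(np.float64)
        n = grey.size
        expected = 255 * 0.3
        photon_var = (255**2 / 400.0) * 0.3  # Poisson: var = scale*I in photons
        total_sd = np.sqrt(photon_var + 1.0**2)
        assert abs(grey.mean() - expected) < 3 * total_sd / np.sqrt(n)
        assert abs(grey.var() / (photon_var + 1.0 + 1 / 12) - 1) < 0.2

    def test_noiseless_limit_matches_analytic_render(self):
        cam = CameraConfig(full_width=128, full_height=128, binning=1, photon_scale=None)
        stack, truth = simulate_beads(cam=cam, n_beads=3, sigma_um=2.0, seed=3,
                                      peak_intensity=0.5, background=0.0)
        # peak pixel of each bead is within quantisation of the requested peak
        for cx, cy in truth.payload["centers_px"]:
            peak = stack.frames[0, int(round(cy)) - 1 : int(round(cy)) + 2,
                                int(round(cx)) - 1 : int(round(cx)) + 2].max()
            # sub-pixel centre offsets flatten the peak pixel slightly
            assert abs(int(peak) - 128) <= 4


class TestBeads:
    def test_determinism(self):
        a, _ = simulate_beads(seed=5)
        b, _ = simulate_beads(seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_separation_constraint(self):
        _, truth = simulate_beads(seed=2, n_beads=20, sigma_um=4.0)
        c = np.asarray(truth.payload["centers_px"])
        d = np.hypot(*(c[:, None, :] - c[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 6 * truth.payload["sigma_px"]

    def test_too_crowded_errors(self):
        cam = CameraConfig(full_width=128, full_height=128, binning=1)
        with pytest.raises(ValueError, match="crowded"):
            simulate_beads(cam=cam, n_beads=500, sigma_um=5.4, seed=0)

    def test_render_then_bin_path_consistent_with_direct(self):
        cam = CameraConfig(full_width=256, full_height=256, binning=2,
                           frame_rate_hz=42.0, photon_scale=None)
        direct, truth_d = simulate_beads(cam=cam, n_beads=4, sigma_um=6.0, seed=9)
        slow, truth_s = simulate_beads(cam=cam, n_beads=4, sigma_um=6.0, seed=9,
                                       render_full_frame=True)
        assert direct.frames.shape == slow.frames.shape
        assert direct.pixel_size_um == slow.pixel_size_um == 2.0
        # both paths yield the same fitted width (the truth width)
        for stack in (direct, slow):
            est = fluo.estimate_psf(stack, sigma_guess_px=3.0)
            assert est.sigma_um == pytest.approx(6.0, rel=0.05)


class TestLarva:
    def test_truth_waves_within_span_and_deterministic(self):
        a, truth = simulate_crawling_larva(seed=4, duration_s=6.0)
        b, _ = simulate_crawling_larva(seed=4, duration_s=6.0)
        assert np.array_equal(a.frames, b.frames)
        assert truth.payload["n_waves"] == len(truth.payload["wave_onsets_s"])
        assert all(0 <= t <= 6.0 for t in truth.payload["wave_onsets_s"])

    def test_zero_amplitude_gives_flat_differential(self):
        # freeze the crawl too: a translating body edge differentiates even
        # without any calcium wave
        cfg = LarvaSceneConfig(wave_amplitude=1e-9, crawl_step_um=0.0)
        stack, _ = simulate_crawling_larva(cfg=cfg, seed=0, duration_s=4.0)
        green = extract_channel(stack, "green")
        diff = fluo.time_differential(green, k=4)
        stmap = fluo.spacetime_map(diff)
        # only shot/read noise remains; far below any wave signal
        assert np.abs(stmap.values).max() < 3.0

    def test_roi_phase_lag_head_to_tail(self):
        stack, truth = simulate_crawling_larva(seed=1, duration_s=6.0)
        green = extract_channel(stack, "green")
        head_row = int(truth.payload["head_row_at_t0"]) + 15
        tail_row = int(truth.payload["head_row_at_t0"] + truth.payload["body_length_px"]) - 15
        cx = truth.payload["body_x_center_px"]
        rois = [DiskROI(cx=cx, cy=row, r=4) for row in (tail_row, head_row)]
        peaks = []
        for roi in rois:
            trace = fluo.roi_trace(green, roi)
            sel = (trace.times_s > 0.4) & (trace.times_s < 1.6)  # first wave only
            peaks.append(trace.times_s[sel][np.argmax(trace.values[sel])])
        assert peaks[0] < peaks[1]  # wave reaches the tail ROI before the head ROI

    def test_larva_longer_than_arena_errors(self):
        cfg = LarvaSceneConfig(body_length_um=20000.0)
        with pytest.raises(ValueError, match="arena"):
            simulate_crawling_larva(cfg=cfg, seed=0)

    def test_unresolvable_waves_rejected(self):
        cam = small_cam(frame_rate_hz=2.0)
        with pytest.raises(ValueError, match="unresolvable"):
            simulate_crawling_larva(cam=cam, cfg=LarvaSceneConfig(wave_period_s=1.0), seed=0)


class TestPerFly:
    def test_event_count_follows_protocol(self):
        _, truth = simulate_per_fly(cam=small_cam(), seed=0)
        assert len(truth.payload["extension_intervals"]) == 5
        assert len(truth.payload["stimulus_intervals"]) == 5

    def test_no_red_channel_rejected(self):
        steps = [rig.ProtocolStep(channel="led_ring.blue", value=255, on_duration_us=10**6)]
        with pytest.raises(ValueError, match="red"):
            simulate_per_fly(cam=small_cam(), protocol=steps, seed=0)

    def test_artefact_only_control_has_no_extension(self):
        _, truth = simulate_per_fly(cam=small_cam(), seed=0, extension_enabled=False)
        assert truth.payload["extension_intervals"] == []


class TestFish:
    def test_bout_threshold_in_truth(self):
        _, truth = simulate_tethered_fish(
            cam=small_cam(), stimuli=[(1.0, 0.15), (3.0, 0.6)], seed=0
        )
        assert [len(b) for b in truth.payload["bout_intervals"]] == [0, 1]

    def test_overlapping_stimuli_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_tethered_fish(cam=small_cam(), stimuli=[(1.0, 1.0), (1.5, 0.6)], seed=0)

    def test_empty_stimuli_flat_fins(self):
        stack, truth = simulate_tethered_fish(cam=small_cam(photon_scale=None),
                                              stimuli=[], seed=0)
        trace = fluo.roi_trace(stack, DiskROI(**truth.payload["left_fin_roi"]))
        assert np.ptp(trace.values) == 0


class TestArena:
    def test_determinism_of_truth_tracks(self):
        _, t1 = simulate_arena_flies(seed=11, duration_s=2.0)
        _, t2 = simulate_arena_flies(seed=11, duration_s=2.0)
        assert np.array_equal(t1.payload["tracks_px"], t2.payload["tracks_px"])

    def test_tracks_within_bounds(self):
        stack, truth = simulate_arena_flies(seed=3, duration_s=3.0)
        tracks = np.asarray(truth.payload["tracks_px"])
        assert tracks[..., 0].min() >= 0 and tracks[..., 0].max() < stack.width
        assert tracks[..., 1].min() >= 0 and tracks[..., 1].max() < stack.height

    def test_arena_too_small(self):
        cam = CameraConfig(full_width=64, full_height=64, binning=1)
        with pytest.raises(ValueError, match="too small"):
            simulate_arena_flies(cam=cam, n_flies=50, seed=0)
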