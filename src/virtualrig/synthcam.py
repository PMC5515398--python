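"""Synthetic-scene generator emulating the rig's camera and preparations.

The emulated sensor delivers 2592 x 1944 RGB frames at 15 Hz, or trades
resolution for speed by spatial binning: x2 (1296 x 972) at 42 Hz, x4 at
90 Hz, with an effective pixel size of ~1 µm at peak zoom. Five scenes mirror
the experimental preparations analysed downstream:

* ``simulate_beads`` — a field of sub-resolution fluorescent beads, each an
  integrated 2D Gaussian, for point-spread-function estimation;
* ``simulate_crawling_larva`` — a GCaMP-expressing larva with peristaltic
  calcium waves travelling tail-to-head, for kymograph wave analysis;
* ``simulate_per_fly`` — a tethered fly extending its proboscis after each
  red-light pulse, with a common-mode illumination artefact;
* ``simulate_tethered_fish`` — pectoral-fin swim bouts elicited only by
  stimuli at or above a duration threshold;
* ``simulate_arena_flies`` — dark fly blobs random-walking in an arena, for
  centroid tracking.

Every generator is deterministic given (config, seed) and returns the stack
together with a :class:`GroundTruth` payload recording exactly what was
rendered. Scenes are rendered directly at the binned output geometry for
speed; ``simulate_beads(..., render_full_frame=True)`` provides the slow
render-then-bin path used to validate the binning transform. Photon shot
noise is Poisson, read noise Gaussian, then 8-bit quantisation; set
``photon_scale=None`` for noise-free renders.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import erf

from .stackio import DiskROI, ImageStack, RectROI, bin_spatial, _round_half_up
from . import rig as _rig

__all__ = [
    "CameraConfig",
    "GroundTruth",
    "LarvaSceneConfig",
    "simulate_beads",
    "simulate_crawling_larva",
    "simulate_per_fly",
    "simulate_tethered_fish",
    "simulate_arena_flies",
    "BINNING_FRAME_RATES",
]

# binning factor -> peak frame rate of the emulated sensor
BINNING_FRAME_RATES = {1: 15.0, 2: 42.0, 4: 90.0}


@dataclass(frozen=True)
class CameraConfig:
    """Acquisition geometry and noise model of the virtual camera.

    ``full_width`` x ``full_height`` is the unbinned sensor crop being imaged
    (defaults to the full 5-megapixel sensor); scenes typically use a small
    crop. ``frame_rate_hz=None`` selects the sensor's peak rate for the
    chosen binning. ``photon_scale`` is the mean photon count at analytic
    intensity 1.0 (``None`` disables all noise); ``read_noise_sd`` is in grey
    levels.
    """

    full_width: int = 2592
    full_height: int = 1944
    binning: int = 2
    frame_rate_hz: float | None = None
    pixel_size_um: float = 1.0
    photon_scale: float | None = 800.0
    read_noise_sd: float = 1.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.binning not in BINNING_FRAME_RATES:
            raise ValueError(f"binning must be one of {sorted(BINNING_FRAME_RATES)}")
        if self.full_width % self.binning or self.full_height % self.binning:
            raise ValueError("sensor crop must be divisible by the binning factor")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive or None")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit output is modelled")

    @property
    def rate_hz(self) -> float:
        return self.frame_rate_hz if self.frame_rate_hz is not None else BINNING_FRAME_RATES[self.binning]

    @property
    def out_width(self) -> int:
        return self.full_width // self.binning

    @property
    def out_height(self) -> int:
        return self.full_height // self.binning

    @property
    def out_pixel_size_um(self) -> float:
        return self.pixel_size_um * self.binning


@dataclass
class GroundTruth:
    """Per-scene generator truth against which analyses are validated."""

    kind: str
    payload: dict

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, (RectROI, DiskROI)):
                return o.__dict__
            raise TypeError(f"not JSON-serialisable: {o!r}")

        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "payload": self.payload}, fh, default=default, indent=1)

    def validate_against(self, stack: ImageStack) -> None:
        """Check that truth events lie in the stack's time span and truth
        coordinates lie within the frame bounds."""
        t_end = stack.t0_s + stack.n_frames / stack.frame_rate_hz
        eps = 1e-9

        def check_interval(iv):
            a, b = iv
            if not (stack.t0_s - eps <= a <= b <= t_end + eps):
                raise ValueError(f"truth interval {iv} outside stack span [{stack.t0_s}, {t_end}]")

        def check_point(xy):
            x, y = xy
            if not (0 <= x < stack.width and 0 <= y < stack.height):
                raise ValueError(f"truth coordinate {xy} outside {stack.height}x{stack.width} frame")

        p = self.payload
        for key in ("extension_intervals", "stimulus_intervals"):
            for iv in p.get(key, []):
                check_interval(iv)
        for ivs in p.get("bout_intervals", []):
            for iv in ivs:
                check_interval(iv)
        for t in p.get("wave_onsets_s", []):
            if not (stack.t0_s - eps <= t <= t_end + eps):
                raise ValueError(f"wave onset {t} outside stack span")
        for xy in p.get("centers_px", []):
            check_point(xy)
        tracks = p.get("tracks_px")
        if tracks is not None:
            for track in np.asarray(tracks).reshape(-1, 2):
                check_point(track)


def _expose(intensity: np.ndarray, cam: CameraConfig, rng: np.random.Generator) -> np.ndarray:
    """Analytic intensity in [0, 1] -> Poisson shot noise -> Gaussian read
    noise -> 8-bit quantisation."""
    intensity = np.clip(intensity, 0.0, None)
    if cam.photon_scale is None:
        grey = 255.0 * intensity
    else:
        photons = rng.poisson(intensity * cam.photon_scale)
        grey = 255.0 * photons / cam.photon_scale
        if cam.read_noise_sd > 0:
            grey = grey + rng.normal(0.0, cam.read_noise_sd, size=grey.shape)
    return np.clip(_round_half_up(grey), 0, 255).astype(np.uint8)


def _pixel_gaussian_1d(coords: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Fraction of a unit 1-D Gaussian integrated over unit pixels at ``coords``."""
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((coords + 1.0 - center) / s) - erf((coords - center) / s))


def render_gaussian_spot(
    frame: np.ndarray, cx: float, cy: float, sigma_px: float, peak: float
) -> None:
    """Add an integrated 2-D isotropic Gaussian spot (peak-normalised) in place."""
    h, w = frame.shape
    r = int(math.ceil(5 * sigma_px)) + 1
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    fx = _pixel_gaussian_1d(np.arange(x0, x1, dtype=np.float64), cx, sigma_px)
    fy = _pixel_gaussian_1d(np.arange(y0, y1, dtype=np.float64), cy, sigma_px)
    central = _pixel_gaussian_1d(np.array([-0.5]), 0.0, sigma_px)[0]
    frame[y0:y1, x0:x1] += peak * np.outer(fy, fx) / central**2


# -- bead field ----------------------------------------------------------------


def simulate_beads(
    cam: CameraConfig | None = None,
    n_beads: int = 30,
    sigma_um: float = 5.4,
    seed: int = 0,
    n_frames: int = 1,
    peak_intensity: float = 0.5,
    background: float = 0.02,
    render_full_frame: bool = False,
) -> tuple[ImageStack, GroundTruth]:
    """Render a field of point-source beads for PSF estimation.

    Each bead is an integrated 2-D isotropic Gaussian of s.d.
    ``sigma_um / pixel size`` pixels, placed by rejection sampling with a
    minimum separation of 6 sigma. The default width is the rig's measured
    optical PSF (5.4 µm s.d. at full zoom with ~1 µm pixels). At the default
    ``photon_scale=800`` and ``peak_intensity=0.5`` the peak photon SNR is
    sqrt(400) = 20.
    """
    if cam is None:
        cam = CameraConfig(full_width=512, full_height=512, binning=1, frame_rate_hz=15.0)
    if sigma_um <= 0:
        raise ValueError("sigma_um must be > 0")
    rng = np.random.default_rng(seed)
    if render_full_frame:
        h, w = cam.full_height, cam.full_width
        sigma_px = sigma_um / cam.pixel_size_um
    else:
        h, w = cam.out_height, cam.out_width
        sigma_px = sigma_um / cam.out_pixel_size_um
    margin = 5.0 * sigma_px
    min_sep = 6.0 * sigma_px
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("field too crowded: frame smaller than the bead margin")
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_beads:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                f"field too crowded to place {n_beads} beads at separation >= {min_sep:.1f} px"
            )
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        if all((cx - x) ** 2 + (cy - y) ** 2 >= min_sep**2 for x, y in centers):
            centers.append((cx, cy))
    analytic = np.full((h, w), background, dtype=np.float64)
    for cx, cy in centers:
        render_gaussian_spot(analytic, cx, cy, sigma_px, peak_intensity)
    frames = np.stack([_expose(analytic, cam, rng) for _ in range(n_frames)])
    stack = ImageStack(
        frames=frames,
        frame_rate_hz=cam.rate_hz,
        pixel_size_um=cam.pixel_size_um if render_full_frame else cam.out_pixel_size_um,
    )
    if render_full_frame:
        stack = bin_spatial(stack, cam.binning)
        centers = [((x + 0.5) / cam.binning - 0.5, (y + 0.5) / cam.binning - 0.5) for x, y in centers]
        sigma_px = sigma_px / cam.binning
    truth = GroundTruth(
        kind="beads",
        payload={
            "centers_px": centers,
            "sigma_um": sigma_um,
            "sigma_px": sigma_px,
            "peak_intensity": peak_intensity,
        },
    )
    truth.validate_against(stack)
    return stack, truth


# -- crawling larva ------------------------------------------------------------


@dataclass(frozen=True)
class LarvaSceneConfig:
    """Geometry and dynamics of the peristaltic-wave larva scene.

    A calcium wave starts at the tail every ``wave_period_s`` and travels
    head-ward at ``wave_speed_um_per_s``, locally raising green-channel
    fluorescence by ``wave_amplitude`` over ``baseline`` with a raised-cosine
    profile of full width ``wave_width_um``. The body drifts head-ward by
    ``crawl_step_um`` per wave period.
    """

    body_length_um: float = 4000.0
    body_width_um: float = 500.0
    n_segments: int = 11
    wave_period_s: float = 1.5
    wave_speed_um_per_s: float = 4000.0
    wave_amplitude: float = 0.5
    baseline: float = 0.25
    crawl_step_um: float = 150.0
    wave_width_um: float = 800.0
    wave_start_s: float = 0.5  # first wave onset; leaves the running-average warm-up wave-free

    def __post_init__(self) -> None:
        for name in (
            "body_length_um",
            "body_width_um",
            "wave_period_s",
            "wave_speed_um_per_s",
            "wave_amplitude",
            "baseline",
            "wave_width_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def default_larva_camera() -> CameraConfig:
    """Small-crop camera for the larva scene: the whole animal in frame at
    a coarse (low-zoom) pixel size, at the post-downsampling analysis rate."""
    return CameraConfig(
        full_width=160,
        full_height=256,
        binning=1,
        frame_rate_hz=10.5,
        pixel_size_um=20.0,
        photon_scale=2000.0,
    )


def simulate_crawling_larva(
    cam: CameraConfig | None = None,
    cfg: LarvaSceneConfig | None = None,
    duration_s: float = 7.5,
    seed: int = 0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a crawling GCaMP larva (long body axis vertical, head up).

    Green-channel intensity along the body follows the travelling raised-
    cosine wave; red and blue carry only a dim body silhouette. Truth holds
    the wave onset times, speed and period.
    """
    cam = cam or default_larva_camera()
    cfg = cfg or LarvaSceneConfig()
    rate = cam.rate_hz
    if cfg.wave_period_s * rate < 4:
        raise ValueError("waves unresolvable: wave_period_s x frame rate must be >= 4")
    p = cam.out_pixel_size_um
    h, w = cam.out_height, cam.out_width
    L_px = cfg.body_length_um / p
    half_w_px = 0.5 * cfg.body_width_um / p
    n_frames = int(round(duration_s * rate))
    crawl_px_per_s = cfg.crawl_step_um / cfg.wave_period_s / p
    total_crawl = crawl_px_per_s * duration_s
    y_head0 = h - 1 - 10 - L_px  # head starts above the tail, 10 px bottom margin
    if y_head0 - total_crawl < 5:
        raise ValueError("larva longer than arena over the requested duration")
    transit_s = cfg.body_length_um / cfg.wave_speed_um_per_s
    onsets = []
    k = 0
    while cfg.wave_start_s + k * cfg.wave_period_s + transit_s <= duration_s:
        onsets.append(cfg.wave_start_s + k * cfg.wave_period_s)
        k += 1
    rng = np.random.default_rng(seed)
    cx = w / 2.0
    xx = np.arange(w, dtype=np.float64)
    yy = np.arange(h, dtype=np.float64)
    in_x = np.abs(xx - cx) <= half_w_px
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    for i in range(n_frames):
        t = i / rate
        y_head = y_head0 - crawl_px_per_s * t
        b_um = (yy - y_head) * p  # body coordinate: 0 at head, increasing tail-ward
        in_body_y = (b_um >= 0) & (b_um <= cfg.body_length_um)
        green_axis = np.where(in_body_y, cfg.baseline, 0.0)
        for t_k in onsets:
            if t_k <= t <= t_k + transit_s + cfg.wave_width_um / cfg.wave_speed_um_per_s:
                b_wave = cfg.body_length_um - cfg.wave_speed_um_per_s * (t - t_k)
                d = b_um - b_wave
                inside = in_body_y & (np.abs(d) < cfg.wave_width_um / 2)
                green_axis = green_axis + np.where(
                    inside,
                    cfg.wave_amplitude * 0.5 * (1 + np.cos(2 * np.pi * d / cfg.wave_width_um)),
                    0.0,
                )
        body = np.outer(in_body_y, in_x)
        scene = np.empty((h, w, 3), dtype=np.float64)
        scene[..., 0] = np.where(body, 0.12, 0.02)
        scene[..., 1] = np.outer(green_axis, in_x) + np.where(body, 0.0, 0.02)
        scene[..., 2] = np.where(body, 0.10, 0.02)
        frames[i] = _expose(scene, cam, rng)
    stack = ImageStack(frames=frames, frame_rate_hz=rate, pixel_size_um=p)
    truth = GroundTruth(
        kind="larva",
        payload={
            "wave_onsets_s": onsets,
            "wave_speed_um_per_s": cfg.wave_speed_um_per_s,
            "wave_period_s": cfg.wave_period_s,
            "n_waves": len(onsets),
            "long_axis": "rows",
            "body_x_center_px": cx,
            "body_half_width_px": half_w_px,
            "head_row_at_t0": y_head0,
            "body_length_px": L_px,
        },
    )
    truth.validate_against(stack)
    return stack, truth


# -- tethered fly, proboscis extension ----------------------------------------


def default_per_protocol() -> list[_rig.ProtocolStep]:
    """All 12 red LEDs at maximum, 1 s on / 2 s off, five repeats."""
    return [
        _rig.ProtocolStep(
            channel="led_ring.red", value=255, on_duration_us=1_000_000,
            off_duration_us=2_000_000, repeats=5,
        )
    ]


def simulate_per_fly(
    cam: CameraConfig | None = None,
    protocol: Sequence[_rig.ProtocolStep] | _rig.EventLog | None = None,
    latency_s: float = 0.1,
    seed: int = 0,
    extension_enabled: bool = True,
    artefact_grey: float = 10.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a tethered fly whose proboscis extends after each red pulse.

    During every red-LED stimulus the whole frame gains a uniform
    ``artefact_grey`` illumination artefact (default 10 grey levels), so the
    analysis chain must remove it by background-over-time subtraction; the
    proboscis tip brightens a known tip ROI from ``latency_s`` after stimulus
    onset until ``latency_s`` after offset. ``extension_enabled=False`` gives
    the artefact-only control. Truth holds both interval lists and the tip ROI.
    """
    if cam is None:
        cam = CameraConfig(
            full_width=128, full_height=96, binning=1, frame_rate_hz=42.0,
            pixel_size_um=10.0, photon_scale=1000.0,
        )
    if protocol is None:
        protocol = default_per_protocol()
    log = protocol if isinstance(protocol, _rig.EventLog) else _rig.compile_protocol(protocol)
    stim = _rig.stimulus_intervals(log, "led_ring.red")
    if not any(e.channel == "led_ring.red" for e in log):
        raise ValueError("protocol addresses no red-LED channel")
    extension = [(a + latency_s, b + latency_s) for a, b in stim] if extension_enabled else []
    duration_s = (log.span_us / 1e6 if len(log) else 0.0) + latency_s + 1.0
    rate = cam.rate_hz
    h, w = cam.out_height, cam.out_width
    n_frames = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # fly body: ellipse in the lower half; proboscis tip site above the head
    body = ((xx - w / 2) / (w * 0.18)) ** 2 + ((yy - h * 0.65) / (h * 0.22)) ** 2 <= 1.0
    tip_cx, tip_cy = w / 2.0, h * 0.28
    tip_roi = DiskROI(cx=tip_cx, cy=tip_cy, r=6.0, label="proboscis_tip")
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    for i in range(n_frames):
        t = i / rate
        base = np.where(body, 0.40, 0.05)
        if any(a <= t < b for a, b in extension):
            tip = np.zeros((h, w))
            render_gaussian_spot(tip, tip_cx, tip_cy, 3.0, 0.45)
            base = base + tip
        scene = np.repeat(base[..., None], 3, axis=-1)
        if any(a <= t < b for a, b in stim):
            scene = scene + artefact_grey / 255.0
        frames[i] = _expose(scene, cam, rng)
    stack = ImageStack(frames=frames, frame_rate_hz=rate, pixel_size_um=cam.out_pixel_size_um)
    truth = GroundTruth(
        kind="per_fly",
        payload={
            "extension_intervals": extension,
            "stimulus_intervals": stim,
            "tip_roi": {"cx": tip_cx, "cy": tip_cy, "r": 6.0},
            "latency_s": latency_s,
            "artefact_grey": artefact_grey,
        },
    )
    truth.validate_against(stack)
    return stack, truth


# -- tethered fish, fin bouts --------------------------------------------------


def simulate_tethered_fish(
    cam: CameraConfig | None = None,
    stimuli: Sequence[tuple[float, float]] = ((1.0, 0.6),),
    threshold_s: float = 0.5,
    seed: int = 0,
    latency_s: float = 0.1,
    bout_duration_s: float = 0.8,
) -> tuple[ImageStack, GroundTruth]:
    """Render a tethered larval zebrafish whose pectoral fins burst into a
    swim bout after each sufficiently long stimulus.

    ``stimuli`` is a list of ``(onset_s, duration_s)``. A stimulus elicits one
    bout (brightness burst in both fin ROIs, 3 Hz modulated, starting
    ``latency_s`` after onset) iff its duration is at least ``threshold_s``
    (default 0.5 s, the shortest reliably effective stimulus on the physical
    rig; ~150 ms stimuli do nothing). The transition is modelled as sharp.
    """
    if cam is None:
        cam = CameraConfig(
            full_width=128, full_height=96, binning=1, frame_rate_hz=42.0,
            pixel_size_um=10.0, photon_scale=1000.0,
        )
    stimuli = sorted(stimuli)
    for (a1, d1), (a2, _) in zip(stimuli, stimuli[1:]):
        if a1 + d1 > a2:
            raise ValueError("stimuli overlap")
    rate = cam.rate_hz
    h, w = cam.out_height, cam.out_width
    end = max((a + d for a, d in stimuli), default=0.0)
    duration_s = end + latency_s + bout_duration_s + 1.0
    n_frames = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    body = ((xx - w / 2) / (w * 0.08)) ** 2 + ((yy - h / 2) / (h * 0.35)) ** 2 <= 1.0
    fin_r = 5.0
    left_roi = DiskROI(cx=w / 2 - w * 0.16, cy=h * 0.40, r=fin_r, label="left_fin")
    right_roi = DiskROI(cx=w / 2 + w * 0.16, cy=h * 0.40, r=fin_r, label="right_fin")
    fin_masks = [roi.mask(h, w) for roi in (left_roi, right_roi)]
    bouts = [
        [(a + latency_s, a + latency_s + bout_duration_s)] if d >= threshold_s else []
        for a, d in stimuli
    ]
    all_bouts = [iv for per_stim in bouts for iv in per_stim]
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    for i in range(n_frames):
        t = i / rate
        scene = np.where(body, 0.35, 0.05)
        fin_level = 0.10
        for a, b in all_bouts:
            if a <= t < b:
                fin_level = 0.10 + 0.40 * 0.5 * (1 - np.cos(2 * np.pi * 3.0 * (t - a)))
                break
        for m in fin_masks:
            scene = np.where(m, fin_level, scene)
        frames[i] = _expose(np.repeat(scene[..., None], 3, axis=-1), cam, rng)
    stack = ImageStack(frames=frames, frame_rate_hz=rate, pixel_size_um=cam.out_pixel_size_um)
    truth = GroundTruth(
        kind="fish",
        payload={
            "stimulus_intervals": [(a, a + d) for a, d in stimuli],
            "bout_intervals": bouts,
            "threshold_s": threshold_s,
            "latency_s": latency_s,
            "left_fin_roi": {"cx": left_roi.cx, "cy": left_roi.cy, "r": fin_r},
            "right_fin_roi": {"cx": right_roi.cx, "cy": right_roi.cy, "r": fin_r},
        },
    )
    truth.validate_against(stack)
    return stack, truth


# -- multi-fly arena -----------------------------------------------------------


def simulate_arena_flies(
    cam: CameraConfig | None = None,
    n_flies: int = 5,
    duration_s: float = 10.0,
    seed: int = 0,
    speed_px_per_frame: float = 2.0,
    blob_radius_px: float = 4.0,
    min_separation_px: float = 32.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render dark fly blobs performing reflecting random walks on a light
    arena floor, with pairwise repulsion keeping a minimum separation.

    Truth holds the per-frame centroid of every fly with persistent identity.
    """
    if cam is None:
        cam = CameraConfig(
            full_width=256, full_height=256, binning=1, frame_rate_hz=15.0,
            pixel_size_um=40.0, photon_scale=2000.0,
        )
    rate = cam.rate_hz
    h, w = cam.out_height, cam.out_width
    margin = blob_radius_px + 3
    if (w - 2 * margin) * (h - 2 * margin) < n_flies * min_separation_px**2:
        raise ValueError("arena too small for the requested flies at minimum separation")
    rng = np.random.default_rng(seed)
    pos = np.empty((n_flies, 2))
    placed = 0
    attempts = 0
    while placed < n_flies:
        attempts += 1
        if attempts > 20000:
            raise ValueError("arena too small: cannot place flies at minimum separation")
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(cand - pos[j])) >= min_separation_px for j in range(placed)):
            pos[placed] = cand
            placed += 1
    angles = rng.uniform(0, 2 * np.pi, size=n_flies)
    n_frames = int(round(duration_s * rate))
    tracks = np.empty((n_flies, n_frames, 2))
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for i in range(n_frames):
        tracks[:, i] = pos
        scene = np.full((h, w), 0.80)
        for j in range(n_flies):
            d2 = (xx - pos[j, 0]) ** 2 + (yy - pos[j, 1]) ** 2
            scene = np.where(d2 <= blob_radius_px**2, 0.15, scene)
        frames[i] = _expose(scene, cam, rng)
        # advance the walk
        angles += rng.normal(0.0, 0.3, size=n_flies)
        step = speed_px_per_frame * np.column_stack([np.cos(angles), np.sin(angles)])
        pos = pos + step
        # pairwise repulsion below 60% of the minimum separation
        for a in range(n_flies):
            for b in range(a + 1, n_flies):
                delta = pos[a] - pos[b]
                dist = np.hypot(*delta)
                if dist < 0.6 * min_separation_px and dist > 0:
                    push = (0.6 * min_separation_px - dist) / 2
                    pos[a] += delta / dist * push
                    pos[b] -= delta / dist * push
        # reflect at walls
        for j in range(n_flies):
            for k, lim in ((0, w), (1, h)):
                if pos[j, k] < margin:
                    pos[j, k] = 2 * margin - pos[j, k]
                    angles[j] = np.pi - angles[j] if k == 0 else -angles[j]
                elif pos[j, k] > lim - margin:
                    pos[j, k] = 2 * (lim - margin) - pos[j, k]
                    angles[j] = np.pi - angles[j] if k == 0 else -angles[j]
    stack = ImageStack(frames=frames, frame_rate_hz=rate, pixel_size_um=cam.out_pixel_size_um)
    truth = GroundTruth(
        kind="arena",
        payload={
            "tracks_px": tracks,
            "blob_radius_px": blob_radius_px,
            "min_separation_px": min_separation_px,
        },
    )
    truth.validate_against(stack)
    return stack, truth
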