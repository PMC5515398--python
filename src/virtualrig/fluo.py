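"""Fluorescence analysis: background subtraction, ROI traces, running-average
time-differential stacks, space-time (kymograph) maps, travelling-wave
detection, and PSF estimation from bead fields.

The calcium workflow mirrors the rig's larval GCaMP analysis: subtract the
background, place ROIs, build the running-average time-differential (each
frame minus the mean of the four preceding frames), collapse the short body
axis into a space-time plot, and read peristaltic waves off its diagonal
ridges. The kymograph position axis is image rows; rotating the long body
axis vertical beforehand is the caller's responsibility.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage, optimize
from scipy.special import erf
from skimage.feature import peak_local_max

from .stackio import ImageStack, ROI, Trace

__all__ = [
    "SpaceTimeMap",
    "WaveEvent",
    "PsfEstimate",
    "subtract_background",
    "roi_trace",
    "time_differential",
    "spacetime_map",
    "detect_waves",
    "estimate_psf",
]


@dataclass
class SpaceTimeMap:
    """Position x time matrix: one column per frame, rows are body-axis bins."""

    values: np.ndarray  # (P, T)
    pos_spacing_um: float
    time_spacing_s: float
    t0_s: float = 0.0
    pos_label: str = "rows"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("space-time map must be 2-D (positions x time)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("space-time map must hold finite values")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, delimiter=",",
                   header=f"pos_spacing_um={self.pos_spacing_um},time_spacing_s={self.time_spacing_s},t0_s={self.t0_s}")


@dataclass(frozen=True)
class WaveEvent:
    """One detected travelling wave (a diagonal ridge in the kymograph)."""

    onset_s: float
    end_s: float
    speed_um_per_s: float
    direction: Literal["head-ward", "tail-ward"]
    peak_differential: float

    def __post_init__(self) -> None:
        if not self.end_s > self.onset_s:
            raise ValueError("wave end must follow onset")
        if self.speed_um_per_s <= 0:
            raise ValueError("wave speed must be positive")


@dataclass
class PsfEstimate:
    """Summary of per-bead Gaussian fits; sigma_um is the median width."""

    sigma_um: float
    beads: list[dict]  # per-bead: cx, cy, sigma_px, amplitude, offset, residual
    n_beads_used: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"sigma_um": self.sigma_um, "n_beads_used": self.n_beads_used, "beads": self.beads},
                fh, indent=1,
            )


# -- background subtraction ----------------------------------------------------


def subtract_background(
    stack: ImageStack,
    mode: Literal["static_min_projection", "temporal_median", "frame_background"] = "static_min_projection",
) -> ImageStack:
    """Subtract an estimated background, clipping at zero.

    ``static_min_projection`` subtracts the per-pixel minimum over time
    (removes a static arena floor); ``temporal_median`` the per-pixel
    temporal median (robust to brief local events); ``frame_background`` the
    spatial median of each frame — the background level *over time* — which
    removes frame-wide, time-varying illumination artefacts such as the
    stimulation-light flash in the proboscis-extension recordings. The
    background is retained in ``result.meta["background"]``.
    """
    if stack.n_frames < 2:
        raise ValueError("background subtraction needs at least 2 frames")
    data = stack.frames.astype(np.float64)
    if mode == "static_min_projection":
        background = data.min(axis=0)
    elif mode == "temporal_median":
        background = np.median(data, axis=0)
    elif mode == "frame_background":
        per_frame = np.median(data, axis=tuple(range(1, data.ndim)))
        out = np.clip(data - per_frame.reshape((-1,) + (1,) * (data.ndim - 1)), 0, None)
        if stack.frames.dtype == np.uint8:
            out = out.astype(np.uint8)
        result = replace(stack, frames=out)
        result.meta["background"] = per_frame
        return result
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = np.clip(data - background, 0, None)
    if stack.frames.dtype == np.uint8:
        out = out.astype(np.uint8)
    result = replace(stack, frames=out)
    result.meta["background"] = background
    return result


def roi_trace(stack: ImageStack, roi: ROI) -> Trace:
    """Per-frame mean intensity over the ROI's pixels."""
    mask = roi.mask(stack.height, stack.width)
    data = stack.frames
    if stack.n_channels == 3:
        values = data[:, mask].mean(axis=(1, 2))
    else:
        values = data[:, mask].mean(axis=1)
    return Trace(times_s=stack.times_s, values=values, units="au")


# -- time differential and kymograph ------------------------------------------


def time_differential(stack: ImageStack, k: int = 4) -> ImageStack:
    """Running-average time-differential stack.

    Output frame ``t`` (for ``t >= k``) is frame ``t`` minus the mean of the
    ``k`` preceding frames, as signed floats. The first ``k`` frames are
    dropped; the frame rate is preserved and ``t0`` shifts by ``k / rate``.
    """
    if stack.n_channels != 1:
        raise ValueError("time_differential requires a single-channel stack")
    t = stack.n_frames
    if k < 1:
        raise ValueError("window k must be >= 1")
    if k >= t:
        raise ValueError(f"window k={k} must be smaller than the stack length {t}")
    data = stack.frames.astype(np.float64)
    acc = np.zeros_like(data[k:])
    for i in range(k):  # summation order fixed: matches an elementwise loop
        acc += data[i : t - k + i]
    out = data[k:] - acc / k
    return replace(
        stack, frames=out, t0_s=stack.t0_s + k / stack.frame_rate_hz
    )


def spacetime_map(
    stack: ImageStack, long_axis: Literal["rows", "columns"] = "rows"
) -> SpaceTimeMap:
    """Collapse the short body axis: mean across it per frame, one column per
    frame. Typically applied to the time-differential stack."""
    if stack.n_channels != 1:
        raise ValueError("spacetime_map requires a single-channel stack")
    data = stack.frames.astype(np.float64)
    if long_axis == "rows":
        values = data.mean(axis=2).T  # (H, T)
    elif long_axis == "columns":
        values = data.mean(axis=1).T  # (W, T)
    else:
        raise ValueError(f"long_axis must be 'rows' or 'columns', got {long_axis!r}")
    return SpaceTimeMap(
        values=values,
        pos_spacing_um=stack.pixel_size_um,
        time_spacing_s=1.0 / stack.frame_rate_hz,
        t0_s=stack.t0_s,
        pos_label=long_axis,
    )


def detect_waves(
    stmap: SpaceTimeMap,
    min_prominence: float = 0.3,
    min_extent: float = 0.5,
) -> list[WaveEvent]:
    """Detect travelling waves as connected diagonal ridges of positive rate
    of change.

    The positive part of the map is thresholded at ``min_prominence`` times
    its maximum; 8-connected components spanning at least ``min_extent`` of
    the position axis become events. Speed is the least-squares slope of the
    ridge's intensity-weighted position centroids against time, converted by
    the axis spacings; direction is head-ward when the ridge moves toward
    position 0 (the head, with the long axis vertical and head up).
    """
    if stmap.values.size == 0:
        raise ValueError("empty space-time map")
    pos_max = float(stmap.values.max())
    events: list[WaveEvent] = []
    if pos_max <= 0:
        return events
    mask = stmap.values >= min_prominence * pos_max
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    n_pos = stmap.values.shape[0]
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        extent = (rows.max() - rows.min()) / max(n_pos - 1, 1)
        if extent < min_extent:
            continue
        # intensity-weighted ridge centroid per time column
        ts, ps = [], []
        for c in np.unique(cols):
            sel = cols == c
            wgt = stmap.values[rows[sel], c]
            ts.append(c)
            ps.append(np.average(rows[sel], weights=wgt))
        ts = np.asarray(ts, dtype=np.float64)
        ps = np.asarray(ps, dtype=np.float64)
        if ts.size < 2:
            continue
        slope = np.polyfit(ts, ps, 1)[0]  # rows per frame
        speed = abs(slope) * stmap.pos_spacing_um / stmap.time_spacing_s
        if speed <= 0:
            continue
        events.append(
            WaveEvent(
                onset_s=stmap.t0_s + cols.min() * stmap.time_spacing_s,
                end_s=stmap.t0_s + (cols.max() + 1) * stmap.time_spacing_s,
                speed_um_per_s=speed,
                direction="head-ward" if slope < 0 else "tail-ward",
                peak_differential=float(stmap.values[rows, cols].max()),
            )
        )
    events.sort(key=lambda e: e.onset_s)
    return events


# -- PSF estimation ------------------------------------------------------------


def _pixel_gaussian_1d(coords: np.ndarray, center: float, sigma: float) -> np.ndarray:
    s = sigma * math.sqrt(2.0)
    return 0.5 * (erf((coords + 1.0 - center) / s) - erf((coords - center) / s))


def _spot_model(params: np.ndarray, ygrid: np.ndarray, xgrid: np.ndarray) -> np.ndarray:
    amp, cx, cy, sigma, offset = params
    fx = _pixel_gaussian_1d(xgrid, cx, sigma)
    fy = _pixel_gaussian_1d(ygrid, cy, sigma)
    return amp * np.outer(fy, fx) + offset


def estimate_psf(
    stack: ImageStack,
    sigma_guess_px: float = 5.0,
    detect_n_sd: float = 5.0,
    saturation_level: int = 255,
) -> PsfEstimate:
    """Estimate the imaging PSF width from a fluorescent-bead field.

    Candidate spots are local maxima above background + ``detect_n_sd`` noise
    s.d.; spots with saturated pixels, neighbours within six widths, or
    fitting windows crossing the frame border are rejected. Each surviving
    spot is fitted with an integrated 2-D isotropic Gaussian (amplitude,
    centre, sigma, offset) by least squares; the summary ``sigma_um`` is the
    median per-bead sigma times the pixel size (robust to occasional
    mis-detections).
    """
    if stack.n_channels != 1:
        frame = stack.frames.astype(np.float64).mean(axis=(0, 3))
    else:
        frame = stack.frames.astype(np.float64).mean(axis=0)
    background = float(np.median(frame))
    noise_sd = 1.4826 * float(np.median(np.abs(frame - background)))
    if noise_sd == 0:
        noise_sd = max(frame.std() * 0.1, 1e-3)
    threshold = background + detect_n_sd * noise_sd
    min_dist = max(int(round(3 * sigma_guess_px)), 1)
    peaks = peak_local_max(frame, min_distance=min_dist, threshold_abs=threshold)
    if len(peaks) == 0:
        raise ValueError("no spots detected")
    # reject close pairs (within 6 sigma_guess of each other)
    keep = []
    for i, (py, px) in enumerate(peaks):
        d = np.hypot(peaks[:, 0] - py, peaks[:, 1] - px)
        d[i] = np.inf
        if d.min() >= 6 * sigma_guess_px:
            keep.append((py, px))
    win = int(math.ceil(4 * sigma_guess_px))
    h, w = frame.shape
    beads: list[dict] = []
    for py, px in keep:
        y0, y1 = py - win, py + win + 1
        x0, x1 = px - win, px + win + 1
        if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
            continue
        cut = frame[y0:y1, x0:x1]
        if cut.max() >= saturation_level:
            continue
        ygrid = np.arange(y0, y1, dtype=np.float64)
        xgrid = np.arange(x0, x1, dtype=np.float64)
        p0 = np.array([cut.max() - background, float(px), float(py), sigma_guess_px, background])
        try:
            res = optimize.least_squares(
                lambda p: (_spot_model(p, ygrid, xgrid) - cut).ravel(),
                p0,
                bounds=(
                    [0, x0, y0, 0.3, -np.inf],
                    [np.inf, x1, y1, 10 * sigma_guess_px, np.inf],
                ),
            )
        except Exception:
            continue
        amp, cx, cy, sigma, offset = res.x
        beads.append(
            {
                "cx": float(cx),
                "cy": float(cy),
                "sigma_px": float(sigma),
                "amplitude": float(amp),
                "offset": float(offset),
                "residual": float(np.sqrt(np.mean(res.fun**2))),
            }
        )
    if not beads:
        raise ValueError("all candidate spots rejected; no usable fits")
    sigma_px = float(np.median([b["sigma_px"] for b in beads]))
    return PsfEstimate(
        sigma_um=sigma_px * stack.pixel_size_um,
        beads=beads,
        n_beads_used=len(beads),
    )
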