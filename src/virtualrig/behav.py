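"""Behavioural quantification.

Covers the video readouts of the optogenetics workflows: proboscis-extension
(PER) traces from a tip ROI after greyscale conversion and background-over-
time subtraction; generic threshold event detection on traces; automated
larval body-length series (skeleton geodesic, robust to bending); per-
stimulus pectoral-fin bout verdicts; and a minimal greedy nearest-neighbour
centroid tracker for multi-animal arenas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .fluo import roi_trace, subtract_background
from .stackio import ImageStack, ROI, Trace, to_grayscale

__all__ = [
    "EventList",
    "Track",
    "BoutVerdict",
    "ContractionSummary",
    "per_trace",
    "analyze_per",
    "detect_events",
    "larval_length_series",
    "contraction_metrics",
    "fin_bout_detect",
    "track_centroids",
]


@dataclass
class EventList:
    """Disjoint, increasing (onset_s, end_s) intervals detected on a trace."""

    intervals: list[tuple[float, float]]
    threshold_value: float
    source: str = ""

    def __post_init__(self) -> None:
        for (a1, b1), (a2, _) in zip(self.intervals, self.intervals[1:]):
            if a2 < b1:
                raise ValueError("event intervals must be disjoint and increasing")
        for a, b in self.intervals:
            if not b > a:
                raise ValueError("event end must follow onset")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def onsets_s(self) -> list[float]:
        return [a for a, _ in self.intervals]


@dataclass
class Track:
    """One animal's per-frame centroid path (gaps allowed)."""

    identity: int
    frame_indices: list[int]
    times_s: list[float]
    centroids: list[tuple[float, float]]  # (cx, cy)

    def __len__(self) -> int:
        return len(self.frame_indices)


@dataclass(frozen=True)
class BoutVerdict:
    """Per-stimulus fin-bout verdict."""

    stimulus_onset_s: float
    stimulus_duration_s: float
    bout: bool
    latency_s: float | None


@dataclass(frozen=True)
class ContractionSummary:
    """Larval length at fixed offsets around an optogenetic flash."""

    length_pre_mm: float  # t = -1 s
    length_mid_mm: float  # t = +0.5 s
    length_post_mm: float  # t = +5 s
    contraction: float  # 1 - mid/pre
    recovery: float  # post/pre


# -- proboscis extension -------------------------------------------------------


def per_trace(stack: ImageStack, tip_roi: ROI) -> Trace:
    """Mean-brightness trace over the proboscis-tip ROI of a grayscale stack.

    Expects the preprocessing already applied: greyscale conversion and
    background-over-time (temporal median) subtraction; see
    :func:`analyze_per` for the full chain.
    """
    if stack.n_channels != 1:
        raise ValueError("per_trace expects a grayscale stack; convert first")
    return roi_trace(stack, tip_roi)


def analyze_per(stack: ImageStack, tip_roi: ROI, **detect_kwargs) -> tuple[Trace, EventList]:
    """Full PER chain: greyscale -> background-over-time subtraction (the
    per-frame background level, which removes the frame-wide stimulation-
    light artefact) -> tip-ROI trace -> event detection."""
    gray = to_grayscale(stack)
    cleaned = subtract_background(gray, mode="frame_background")
    trace = per_trace(cleaned, tip_roi)
    return trace, detect_events(trace, **detect_kwargs)


# -- event detection -----------------------------------------------------------


def detect_events(
    trace: Trace,
    threshold: float | None = None,
    k_sigma: float = 3.0,
    min_duration_s: float = 0.1,
    min_gap_s: float = 0.1,
) -> EventList:
    """Detect epochs where a trace rises above baseline.

    Baseline is the trace median; the threshold is either ``threshold``
    (absolute) or baseline + ``k_sigma`` x a MAD-derived noise s.d. Runs above
    threshold shorter than ``min_duration_s`` are dropped; runs separated by
    gaps shorter than ``min_gap_s`` are merged first.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    values = trace.values
    baseline = float(np.median(values))
    if threshold is None:
        sigma = 1.4826 * float(np.median(np.abs(values - baseline)))
        threshold = baseline + k_sigma * sigma
    above = values > threshold
    times = trace.times_s
    dt = float(np.median(np.diff(times))) if len(trace) > 1 else 0.0
    raw: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = times[i]
        elif not flag and start is not None:
            raw.append((start, times[i]))
            start = None
    if start is not None:
        raw.append((start, times[-1] + dt))
    merged: list[tuple[float, float]] = []
    for a, b in raw:
        if merged and a - merged[-1][1] < min_gap_s:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    kept = [(a, b) for a, b in merged if b - a >= min_duration_s]
    return EventList(intervals=kept, threshold_value=float(threshold), source=trace.units)


# -- larval length -------------------------------------------------------------


def _segmentation_mask(
    frame: np.ndarray, polarity: Literal["dark_on_light", "light_on_dark"]
) -> np.ndarray:
    if frame.max() == frame.min():
        raise ValueError("no component found: frame is constant")
    thr = threshold_otsu(frame)
    mask = frame < thr if polarity == "dark_on_light" else frame > thr
    if not mask.any():
        raise ValueError("no component found after thresholding")
    labels = cc_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return labels == largest


def _skeleton_geodesic_px(mask: np.ndarray) -> float:
    """Longest geodesic path through the skeleton, plus the end-cap radii.

    The skeleton of an elongated blob stops about one local radius short of
    each end; adding the distance-transform value at the two path extremes
    recovers the full head-to-tail length.
    """
    skel = skeletonize(mask)
    ys, xs = np.nonzero(skel)
    n = ys.size
    if n == 0:
        raise ValueError("no component found: empty skeleton")
    if n == 1:
        return 1.0
    index = -np.ones(mask.shape, dtype=int)
    index[ys, xs] = np.arange(n)
    rows, cols, data = [], [], []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ny, nx = ys + dy, xs + dx
            ok = (0 <= ny) & (ny < mask.shape[0]) & (0 <= nx) & (nx < mask.shape[1])
            ok &= index[ny % mask.shape[0], nx % mask.shape[1]] >= 0
            ok_idx = np.nonzero(ok)[0]
            nbr = index[ny[ok_idx], nx[ok_idx]]
            rows.extend(ok_idx)
            cols.extend(nbr)
            data.extend([np.hypot(dy, dx)] * len(ok_idx))
    graph = csr_matrix((data, (rows, cols)), shape=(n, n))
    # double-sweep: farthest node from an arbitrary start, then farthest from it
    d0 = dijkstra(graph, indices=0)
    d0[~np.isfinite(d0)] = -1
    far = int(np.argmax(d0))
    d1, pred = dijkstra(graph, indices=far, return_predecessors=True)
    d1[~np.isfinite(d1)] = -1
    other = int(np.argmax(d1))
    # reconstruct the path and smooth it: the raw 8-connected staircase
    # over-counts the length of curved digital lines by several percent
    chain = [other]
    while chain[-1] != far:
        chain.append(int(pred[chain[-1]]))
    path = np.column_stack([ys[chain], xs[chain]]).astype(np.float64)
    if len(path) > 7:
        kernel = np.ones(7) / 7
        padded = np.pad(path, ((3, 3), (0, 0)), mode="edge")
        path = np.column_stack(
            [np.convolve(padded[:, 0], kernel, "valid"), np.convolve(padded[:, 1], kernel, "valid")]
        )
    geodesic = float(np.hypot(*np.diff(path, axis=0).T).sum())
    dist = ndimage.distance_transform_edt(mask)
    return geodesic + float(dist[ys[far], xs[far]]) + float(dist[ys[other], xs[other]])


def larval_length_series(
    stack: ImageStack, intensity_polarity: Literal["dark_on_light", "light_on_dark"] = "dark_on_light"
) -> Trace:
    """Automated head-to-tail body length per frame, in millimetres.

    Per frame: Otsu threshold, largest connected component, skeletonise,
    length = longest geodesic skeleton path (plus end caps) x pixel size.
    The geodesic handles bent bodies, where an ellipse major axis or a
    head-tail chord would underestimate the arc length.
    """
    frames = stack.frames if stack.n_channels == 1 else to_grayscale(stack).frames
    lengths = []
    for i in range(stack.n_frames):
        mask = _segmentation_mask(frames[i].astype(np.float64), intensity_polarity)
        lengths.append(_skeleton_geodesic_px(mask) * stack.pixel_size_um / 1000.0)
    return Trace(times_s=stack.times_s, values=np.array(lengths), units="mm")


def contraction_metrics(
    lengths: Trace, flash_onset_s: float, flash_dur_s: float = 1.0
) -> ContractionSummary:
    """Body length at t = -1, +0.5 and +5 s relative to the flash onset
    (nearest sample), with fractional contraction and recovery."""
    offsets = (-1.0, 0.5, 5.0)
    t = lengths.times_s
    picked = []
    for off in offsets:
        target = flash_onset_s + off
        if target < t[0] - 1e-9 or target > t[-1] + 1e-9:
            raise ValueError(
                f"offsets out of range: trace [{t[0]}, {t[-1]}] s does not span t = {target} s"
            )
        picked.append(float(lengths.values[int(np.argmin(np.abs(t - target)))]))
    pre, mid, post = picked
    return ContractionSummary(
        length_pre_mm=pre,
        length_mid_mm=mid,
        length_post_mm=post,
        contraction=1.0 - mid / pre,
        recovery=post / pre,
    )


# -- fin bouts -----------------------------------------------------------------


def fin_bout_detect(
    left: Trace,
    right: Trace,
    stimuli: Sequence[tuple[float, float]],
    response_window_s: float = 1.0,
    **detect_kwargs,
) -> list[BoutVerdict]:
    """Per-stimulus swim-bout verdicts from the two pectoral-fin traces.

    A stimulus scores a bout when event detection fires on either fin trace
    with an onset inside ``(onset, onset + window]``; latency is the first
    such event onset minus the stimulus onset. Response windows of successive
    stimuli must not overlap.
    """
    stimuli = sorted(stimuli)
    for (a1, _), (a2, _) in zip(stimuli, stimuli[1:]):
        if a1 + response_window_s > a2:
            raise ValueError("overlapping response windows")
    events: list[tuple[float, float]] = []
    for trace in (left, right):
        events.extend(detect_events(trace, **detect_kwargs).intervals)
    events.sort()
    verdicts = []
    for onset, dur in stimuli:
        hits = [a for a, _ in events if onset < a <= onset + response_window_s]
        verdicts.append(
            BoutVerdict(
                stimulus_onset_s=onset,
                stimulus_duration_s=dur,
                bout=bool(hits),
                latency_s=(min(hits) - onset) if hits else None,
            )
        )
    return verdicts


# -- centroid tracking ---------------------------------------------------------


def track_centroids(
    stack: ImageStack,
    polarity: Literal["dark_on_light", "light_on_dark"] = "dark_on_light",
    max_jump_px: float = 15.0,
    min_area_px: int = 5,
    max_gap_frames: int = 2,
) -> list[Track]:
    """Minimal multi-animal tracker: per-frame threshold + connected
    components, greedy nearest-neighbour linking under ``max_jump_px``.

    Unmatched detections start new tracks; a track unmatched for more than
    ``max_gap_frames`` consecutive frames is terminated (a detection jumping
    farther than ``max_jump_px`` therefore starts a new identity).
    """
    frames = stack.frames if stack.n_channels == 1 else to_grayscale(stack).frames
    times = stack.times_s
    tracks: list[Track] = []
    active: list[tuple[Track, tuple[float, float], int]] = []  # (track, last pos, last frame)
    next_id = 0
    for i in range(stack.n_frames):
        frame = frames[i].astype(np.float64)
        try:
            mask = _segmentation_mask_all(frame, polarity, min_area_px)
        except ValueError:
            mask = np.zeros(frame.shape, dtype=bool)
        labels, n = ndimage.label(mask)
        detections = [
            (float(cx), float(cy))
            for cy, cx in ndimage.center_of_mass(mask, labels, range(1, n + 1))
        ]
        # greedy matching by ascending distance
        pairs = []
        for ai, (_, pos, _) in enumerate(active):
            for di, det in enumerate(detections):
                d = np.hypot(det[0] - pos[0], det[1] - pos[1])
                if d <= max_jump_px:
                    pairs.append((d, ai, di))
        pairs.sort()
        used_a: set[int] = set()
        used_d: set[int] = set()
        new_active = []
        for d, ai, di in pairs:
            if ai in used_a or di in used_d:
                continue
            used_a.add(ai)
            used_d.add(di)
            track = active[ai][0]
            det = detections[di]
            track.frame_indices.append(i)
            track.times_s.append(float(times[i]))
            track.centroids.append(det)
            new_active.append((track, det, i))
        for ai, (track, pos, last) in enumerate(active):
            if ai not in used_a and i - last <= max_gap_frames:
                new_active.append((track, pos, last))
        for di, det in enumerate(detections):
            if di not in used_d:
                track = Track(
                    identity=next_id,
                    frame_indices=[i],
                    times_s=[float(times[i])],
                    centroids=[det],
                )
                next_id += 1
                tracks.append(track)
                new_active.append((track, det, i))
        active = new_active
    return tracks


def _segmentation_mask_all(
    frame: np.ndarray, polarity: Literal["dark_on_light", "light_on_dark"], min_area_px: int
) -> np.ndarray:
    if frame.max() == frame.min():
        raise ValueError("constant frame")
    thr = threshold_otsu(frame)
    mask = frame < thr if polarity == "dark_on_light" else frame > thr
    labels, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no components")
    areas = np.bincount(labels.ravel())
    small = np.nonzero(areas < min_area_px)[0]
    mask[np.isin(labels, small)] = False
    return mask
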