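"""Image-stack data model, TIFF/AVI I/O and acquisition-convention transforms.

The :class:`ImageStack` is the common currency of the whole toolkit: a
T x H x W (grayscale) or T x H x W x 3 (RGB) pixel array with the acquisition
metadata needed downstream (frame rate, pixel size, start time).  Conventions
used everywhere in this package:

* pixel coordinates are 0-based and row-major, origin at the top-left;
* rectangles are half-open ``[x0, x1) x [y0, y1)``;
* 8-bit stacks hold values in ``[0, 255]``; float stacks hold finite values
  (signed values are legal, e.g. time-differential output).

Stacks are written as multi-page TIFF with a sidecar ``<name>.json`` holding
frame rate, pixel size, start time and channel names — TIFF tags for these
are dialect-ridden, a plain sidecar is not.
"""

from __future__ import annotations

import json
import os
import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "RectROI",
    "DiskROI",
    "Trace",
    "read_stack",
    "write_stack",
    "bin_spatial",
    "downsample_time",
    "extract_channel",
    "to_grayscale",
    "make_output_path",
    "OUTPUT_KINDS",
]

RGB_CHANNEL_NAMES = ("red", "green", "blue")

OUTPUT_KINDS = ("time_lapse", "video", "snapshots", "temperature_logging")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half-up to the nearest integer (np.round rounds half-to-even)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class ImageStack:
    """A time series of frames plus acquisition metadata.

    Parameters
    ----------
    frames
        ``(T, H, W)`` grayscale or ``(T, H, W, 3)`` RGB array, uint8 or float.
    frame_rate_hz
        Acquisition rate; frame ``k`` is timestamped ``t0_s + k / frame_rate_hz``.
    pixel_size_um
        Microns spanned by one pixel (1 µm at peak zoom for the emulated camera).
    t0_s
        Acquisition start time in seconds.
    channel_names
        Per-channel labels for RGB stacks; ``None`` for grayscale.
    meta
        Free-form extras (e.g. the background image retained by
        :func:`virtualrig.fluo.subtract_background`). Not compared in ``==``.
    """

    frames: np.ndarray
    frame_rate_hz: float = 42.0
    pixel_size_um: float = 1.0
    t0_s: float = 0.0
    channel_names: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 3:
            pass
        elif self.frames.ndim == 4 and self.frames.shape[-1] == 3:
            if self.channel_names is None:
                self.channel_names = RGB_CHANNEL_NAMES
        else:
            raise ValueError(
                f"frames must be (T,H,W) or (T,H,W,3); got shape {self.frames.shape}"
            )
        t, h, w = self.frames.shape[:3]
        if t < 1 or h < 1 or w < 1:
            raise ValueError("stack must have T >= 1, H >= 1, W >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if np.issubdtype(self.frames.dtype, np.integer):
            if self.frames.dtype != np.uint8:
                raise ValueError("integer stacks must be 8-bit (uint8)")
        elif not np.all(np.isfinite(self.frames)):
            raise ValueError("float stacks must hold finite values")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else 3

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            self.frames.shape == other.frames.shape
            and self.frames.dtype == other.frames.dtype
            and np.array_equal(self.frames, other.frames)
            and self.frame_rate_hz == other.frame_rate_hz
            and self.pixel_size_um == other.pixel_size_um
            and self.t0_s == other.t0_s
            and self.channel_names == other.channel_names
        )


@dataclass(frozen=True)
class RectROI:
    """Half-open axis-aligned rectangle ``[x0, x1) x [y0, y1)`` in pixels."""

    x0: int
    y0: int
    x1: int
    y1: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError("rectangle requires x1 > x0 and y1 > y0")

    def mask(self, height: int, width: int) -> np.ndarray:
        if self.x0 >= width or self.y0 >= height or self.x1 <= 0 or self.y1 <= 0:
            raise ValueError(f"ROI {self} does not intersect a {height}x{width} frame")
        m = np.zeros((height, width), dtype=bool)
        m[max(self.y0, 0) : min(self.y1, height), max(self.x0, 0) : min(self.x1, width)] = True
        return m


@dataclass(frozen=True)
class DiskROI:
    """Disk of radius ``r`` centred at ``(cx, cy)`` in pixel coordinates."""

    cx: float
    cy: float
    r: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("disk ROI requires r > 0")

    def mask(self, height: int, width: int) -> np.ndarray:
        yy, xx = np.mgrid[0:height, 0:width]
        m = (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.r**2
        if not m.any():
            raise ValueError(f"ROI {self} does not intersect a {height}x{width} frame")
        return m


ROI = RectROI | DiskROI


@dataclass
class Trace:
    """A sampled scalar time series (fluorescence, length, temperature...)."""

    times_s: np.ndarray
    values: np.ndarray
    units: str = "au"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and values must be equal-length 1-D arrays")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size

    def to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# units: {self.units}\n")
            fh.write("time_s,value\n")
            for t, v in zip(self.times_s, self.values):
                fh.write(f"{float(t)!r},{float(v)!r}\n")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "Trace":
        units = "au"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# units:"):
                units = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
        return cls(times_s=data[:, 0], values=data[:, 1], units=units)


# -- file I/O ------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a multi-page TIFF plus a sidecar JSON with the metadata.

    Lossless for 8-bit stacks: ``read_stack(write_stack(s)) == s``.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    photometric = "rgb" if stack.n_channels == 3 else "minisblack"
    tifffile.imwrite(path, stack.frames, photometric=photometric)
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_size_um": stack.pixel_size_um,
        "t0_s": stack.t0_s,
        "channel_names": list(stack.channel_names) if stack.channel_names else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | os.PathLike) -> ImageStack:
    """Read a multi-page TIFF (or AVI) into an :class:`ImageStack`.

    Metadata comes from the sidecar ``<name>.json`` when present, else the
    documented defaults (42 Hz, 1 µm pixels, t0 = 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".avi", ".mp4", ".mov"}:
        frames = _read_movie(path)
    else:
        try:
            frames = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"unreadable container: {path} ({exc})") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError(f"unreadable container: {path} holds zero frames")
    kwargs: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kwargs = {
            "frame_rate_hz": meta.get("frame_rate_hz", 42.0),
            "pixel_size_um": meta.get("pixel_size_um", 1.0),
            "t0_s": meta.get("t0_s", 0.0),
        }
        if meta.get("channel_names"):
            kwargs["channel_names"] = tuple(meta["channel_names"])
    return ImageStack(frames=frames, **kwargs)


def _read_movie(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        return np.asarray(iio.imread(path, index=None))
    except Exception as exc:  # no ffmpeg plugin, truncated file, ...
        raise ValueError(f"unreadable container: {path} ({exc})") from exc


# -- acquisition-convention transforms ----------------------------------------


def bin_spatial(stack: ImageStack, factor: int) -> ImageStack:
    """Block-mean over ``factor x factor`` tiles (the camera's spatial binning).

    The emulated sensor delivers full frames at 15 Hz and trades resolution
    for speed: x2 binning (1296 x 972 from 2592 x 1944) at 42 Hz, x4 at 90 Hz.
    8-bit stacks are rounded half-up back to uint8; pixel size scales by
    ``factor``.
    """
    if factor not in (1, 2, 4):
        raise ValueError(f"unsupported binning factor {factor}; expected 1, 2 or 4")
    if factor == 1:
        return replace(stack, frames=stack.frames.copy())
    t, h, w = stack.frames.shape[:3]
    if h % factor or w % factor:
        raise ValueError(f"frame size {h}x{w} not divisible by factor {factor}")
    shape = (t, h // factor, factor, w // factor, factor) + stack.frames.shape[3:]
    blocks = stack.frames.reshape(shape).astype(np.float64)
    out = blocks.mean(axis=(2, 4))
    if stack.frames.dtype == np.uint8:
        out = _round_half_up(out).astype(np.uint8)
    return replace(stack, frames=out, pixel_size_um=stack.pixel_size_um * factor)


def downsample_time(
    stack: ImageStack, factor: int, method: Literal["mean", "decimate"] = "mean"
) -> ImageStack:
    """Temporal downsampling by non-overlapping blocks of ``factor`` frames.

    Default is block-averaging (improves SNR); ``method="decimate"`` keeps the
    first frame of each block instead. A trailing partial block is dropped.
    The frame rate divides by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    t = stack.n_frames
    if factor > t:
        raise ValueError(f"factor {factor} exceeds stack length {t}")
    n = t // factor
    trimmed = stack.frames[: n * factor]
    if method == "decimate":
        out = trimmed[::factor].copy()
    else:
        blocks = trimmed.reshape((n, factor) + stack.frames.shape[1:]).astype(np.float64)
        out = blocks.mean(axis=1)
        if stack.frames.dtype == np.uint8:
            out = _round_half_up(out).astype(np.uint8)
    return replace(stack, frames=out, frame_rate_hz=stack.frame_rate_hz / factor)


def extract_channel(stack: ImageStack, channel: str) -> ImageStack:
    """Extract one colour plane of an RGB stack as a grayscale stack."""
    if stack.n_channels != 3:
        raise ValueError("channel extraction requires an RGB stack")
    names = stack.channel_names or RGB_CHANNEL_NAMES
    if channel not in names:
        raise ValueError(f"unknown channel {channel!r}; stack has {names}")
    idx = names.index(channel)
    return replace(stack, frames=stack.frames[..., idx].copy(), channel_names=None)


def to_grayscale(
    stack: ImageStack, weighting: Literal["mean", "luminance"] = "mean"
) -> ImageStack:
    """Convert RGB to 8-bit grayscale.

    Default is the unweighted mean of R, G, B rounded half-up; ITU-R BT.601
    luminance weighting (0.299, 0.587, 0.114) is available behind the
    ``weighting`` flag. Grayscale input is returned unchanged (a copy).
    """
    if stack.n_channels == 1:
        return replace(stack, frames=stack.frames.copy())
    w = np.array([1 / 3, 1 / 3, 1 / 3]) if weighting == "mean" else np.array(
        [0.299, 0.587, 0.114]
    )
    gray = np.tensordot(stack.frames.astype(np.float64), w, axes=([-1], [0]))
    if stack.frames.dtype == np.uint8:
        gray = np.clip(_round_half_up(gray), 0, 255).astype(np.uint8)
    return replace(stack, frames=gray, channel_names=None)


# -- output-folder layout ------------------------------------------------------


def make_output_path(
    root: str | os.PathLike,
    kind: str,
    clock: Callable[[], datetime] | None = None,
) -> Path:
    """Create and return a fresh timestamped output directory.

    Layout is ``<root>/FlyPi_output/<kind>/<ISO-8601 timestamp>`` with a
    numeric suffix appended on collision, so repeated calls within the same
    second never overwrite earlier data. The directory is created.
    """
    if kind not in OUTPUT_KINDS:
        raise ValueError(f"unknown output kind {kind!r}; expected one of {OUTPUT_KINDS}")
    now = (clock or datetime.now)()
    stamp = now.strftime("%Y-%m-%dT%H-%M-%S")
    base = Path(root) / "FlyPi_output" / kind
    base.mkdir(parents=True, exist_ok=True)
    candidate = base / stamp
    suffix = 0
    while True:
        try:
            candidate.mkdir()
            return candidate
        except FileExistsError:
            suffix += 1
            candidate = base / f"{stamp}_{suffix:03d}"
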