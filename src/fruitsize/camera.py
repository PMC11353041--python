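"""Pinhole-camera conversions between pixels, depth, and metric size.

The detection's bounding-box centre, sampled against the aligned depth
raster, back-projects to camera-frame coordinates::

    x = (px - ppx) / fx * z        y = (py - ppy) / fy * z

Per-frame 3D positions are averaged over a trailing window (default 10
frames) to suppress depth noise, and a fitted pixel radius converts to a
metric diameter by similar triangles::

    diameter_mm = 2 * r_px * z * 1000 / f

with ``f`` the mean of ``fx`` and ``fy`` by default (near-square pixels).

Units: depth rasters are 16-bit integers in millimetres with 0 marking
invalid returns; all camera-frame coordinates are metres; reported
diameters are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import yaml

from .errors import InvalidDepthError, NonPositiveInputError, ShortSeriesError
from .imaging import BBox

__all__ = [
    "Intrinsics",
    "Point3D",
    "bbox_center",
    "sample_depth",
    "backproject",
    "average_frames",
    "pixel_radius_to_mm",
]


class Point3D(NamedTuple):
    """Camera-frame coordinates in metres."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsics: principal point and focal lengths in pixels.

    ``width``/``height`` describe the sensor frame the parameters refer
    to; ``depth_scale`` converts raw depth-raster units to millimetres
    (1.0 for the conventional millimetre raster).
    """

    ppx: float
    ppy: float
    fx: float
    fy: float
    width: int = 640
    height: int = 480
    depth_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (-self.width <= self.ppx <= 2 * self.width
                and -self.height <= self.ppy <= 2 * self.height):
            raise ValueError("principal point implausibly far outside the frame")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    @property
    def f_mean(self) -> float:
        return 0.5 * (self.fx + self.fy)

    @classmethod
    def from_file(cls, path: str | Path) -> "Intrinsics":
        """Load from YAML or JSON with keys ppx, ppy, fx, fy, [width, height, depth_scale]."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of intrinsics keys")
        known = {"ppx", "ppy", "fx", "fy", "width", "height", "depth_scale"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown intrinsics keys {sorted(unknown)}")
        missing = {"ppx", "ppy", "fx", "fy"} - set(data)
        if missing:
            raise ValueError(f"{path}: missing intrinsics keys {sorted(missing)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "ppx": self.ppx, "ppy": self.ppy, "fx": self.fx, "fy": self.fy,
            "width": self.width, "height": self.height, "depth_scale": self.depth_scale,
        }


def bbox_center(b: BBox) -> tuple[float, float]:
    """Arithmetic midpoint of a bounding box, unrounded."""
    return (b.xmin + b.xmax) / 2.0, (b.ymin + b.ymax) / 2.0


def sample_depth(
    depth: np.ndarray,
    px: float,
    py: float,
    mode: Literal["nearest", "median3"] = "nearest",
    *,
    scale_mm: float = 1.0,
) -> float:
    """Depth at a pixel position, in metres.

    ``nearest`` reads the nearest pixel; ``median3`` takes the median of
    the valid (non-zero) values in the 3x3 neighbourhood, which tolerates
    single-pixel sensor dropouts.  Raw units are converted to millimetres
    by ``scale_mm`` and then to metres.

    Raises :class:`InvalidDepthError` when no valid sample exists.
    """
    d = np.asarray(depth)
    if d.ndim != 2:
        raise ValueError("depth frame must be 2D")
    h, w = d.shape
    col = int(round(px))
    row = int(round(py))
    if not (0 <= col < w and 0 <= row < h):
        raise ValueError(f"point ({px}, {py}) outside {w}x{h} depth frame")
    if mode == "nearest":
        raw = float(d[row, col])
        if raw <= 0:
            raise InvalidDepthError(f"no depth return at ({col}, {row})")
        return raw * scale_mm / 1000.0
    if mode == "median3":
        window = d[max(row - 1, 0): row + 2, max(col - 1, 0): col + 2].astype(float)
        valid = window[window > 0]
        if valid.size == 0:
            raise InvalidDepthError(f"no valid depth in 3x3 window at ({col}, {row})")
        return float(np.median(valid)) * scale_mm / 1000.0
    raise ValueError(f"unknown depth sampling mode {mode!r}")


def backproject(px: float, py: float, z: float, K: Intrinsics) -> Point3D:
    """Back-project a pixel with depth ``z`` (metres) to camera coordinates."""
    if z <= 0:
        raise InvalidDepthError(f"depth must be positive, got {z}")
    x = (px - K.ppx) / K.fx * z
    y = (py - K.ppy) / K.fy * z
    return Point3D(float(x), float(y), float(z))


def average_frames(series: Sequence[Point3D] | Iterable, window: int = 10) -> Point3D:
    """Componentwise mean of the last ``window`` frames of a 3D series.

    Raises :class:`ShortSeriesError` when fewer than ``window`` frames
    are available.
    """
    arr = np.asarray([tuple(p) for p in series], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("series must be a sequence of (x, y, z) triples")
    if window < 1:
        raise ValueError("window must be >= 1")
    if arr.shape[0] < window:
        raise ShortSeriesError(f"need {window} frames, got {arr.shape[0]}")
    tail = arr[-window:]
    return Point3D(*map(float, tail.mean(axis=0)))


def pixel_radius_to_mm(
    r_px: float,
    z: float,
    K: Intrinsics,
    focal: Literal["mean", "fx", "fy"] = "mean",
) -> float:
    """Metric diameter (mm) of a circle of pixel radius ``r_px`` at depth ``z``.

    ``diameter_mm = 2 * r_px * z * 1000 / f`` with ``f`` selected by
    ``focal`` (default: mean of fx and fy).
    """
    if r_px <= 0:
        raise NonPositiveInputError(f"pixel radius must be positive, got {r_px}")
    if z <= 0:
        raise NonPositiveInputError(f"depth must be positive, got {z}")
    f = {"mean": K.f_mean, "fx": K.fx, "fy": K.fy}.get(focal)
    if f is None:
        raise ValueError(f"unknown focal mode {focal!r}")
    return 2.0 * r_px * z * 1000.0 / f
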