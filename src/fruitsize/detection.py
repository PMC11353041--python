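"""Bounding-box providers for the sizing pipeline.

The sizing stages consume plain :class:`Detection` records, so any
detector can drive them: a trained network whose outputs are replayed
from a CSV/JSON file (:func:`load_detections`), a user-registered
callable (:func:`register_detector`), or the built-in colour-threshold
baseline that localises red fruit on synthetic or real scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import pandas as pd
from skimage import measure

from .errors import DetectionParseError, ImageFormatError
from .imaging import BBox

__all__ = [
    "Detection",
    "ThresholdConfig",
    "detect_baseline",
    "load_detections",
    "save_detections",
    "register_detector",
    "get_detector",
]

DEFAULT_LABEL = "goodapple"


@dataclass(frozen=True)
class Detection:
    """One detected fruit: box, confidence in [0, 1], class label."""

    bbox: BBox
    confidence: float = 1.0
    label: str = DEFAULT_LABEL

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Colour-threshold settings of the baseline detector.

    A pixel is fruit-candidate when its red excess
    ``R - (G + B) / 2`` exceeds ``red_excess``; candidate regions are
    connected components of that mask.
    """

    red_excess: float = 40.0

    def __post_init__(self) -> None:
        if self.red_excess <= 0:
            raise ValueError("red_excess must be positive")


def detect_baseline(
    image: np.ndarray,
    min_area: float = 150.0,
    threshold_config: ThresholdConfig | None = None,
) -> list[Detection]:
    """Colour-threshold + connected-components fruit detector.

    Deterministic stand-in for a trained detector: red-excess
    thresholding, 8-connected component labelling, and an area filter.
    Boxes are the tight component bounds; confidence is the component's
    solidity (area over convex-hull area).  Detections are ordered by
    ``(ymin, xmin)``.
    """
    if threshold_config is None:
        threshold_config = ThresholdConfig()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ImageFormatError("baseline detector requires a 3-channel RGB image")
    rgb = img.astype(float)
    excess = rgb[:, :, 0] - 0.5 * (rgb[:, :, 1] + rgb[:, :, 2])
    mask = excess > threshold_config.red_excess
    labels = measure.label(mask, connectivity=2)
    out: list[Detection] = []
    for props in measure.regionprops(labels):
        if props.area < min_area:
            continue
        minr, minc, maxr, maxc = props.bbox
        confidence = float(np.clip(props.solidity, 0.0, 1.0))
        out.append(
            Detection(BBox(minc, minr, maxc, maxr), confidence=confidence)
        )
    out.sort(key=lambda det: (det.bbox.ymin, det.bbox.xmin))
    return out


_COLUMNS = ["xmin", "ymin", "xmax", "ymax", "confidence", "label"]


def _detection_from_row(row: dict, where: str) -> Detection:
    try:
        bbox = BBox(
            float(row["xmin"]), float(row["ymin"]),
            float(row["xmax"]), float(row["ymax"]),
        )
        return Detection(
            bbox,
            confidence=float(row.get("confidence", 1.0)),
            label=str(row.get("label", DEFAULT_LABEL)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DetectionParseError(f"{where}: {exc}") from exc


def load_detections(path: str | Path) -> list[Detection]:
    """Read detections from CSV or JSON.

    CSV needs columns ``xmin, ymin, xmax, ymax`` and optionally
    ``confidence`` and ``label``; JSON is a list of objects with the same
    keys.  Malformed rows raise :class:`DetectionParseError` naming the
    offending row.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        try:
            rows = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise DetectionParseError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(rows, list):
            raise DetectionParseError(f"{path}: expected a JSON list of detections")
        return [
            _detection_from_row(row, f"{path} entry {i}") for i, row in enumerate(rows)
        ]
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DetectionParseError(f"{path}: {exc}") from exc
    missing = {"xmin", "ymin", "xmax", "ymax"} - set(frame.columns)
    if missing:
        raise DetectionParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        _detection_from_row(row, f"{path} row {i}")
        for i, row in frame.iterrows()
    ]


def save_detections(detections: list[Detection], path: str | Path) -> None:
    """Write detections to CSV with the canonical column order."""
    rows = [
        {
            "xmin": det.bbox.xmin, "ymin": det.bbox.ymin,
            "xmax": det.bbox.xmax, "ymax": det.bbox.ymax,
            "confidence": det.confidence, "label": det.label,
        }
        for det in detections
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- adapters

DetectorFn = Callable[[np.ndarray], list[Detection]]
_REGISTRY: dict[str, DetectorFn] = {}


def register_detector(name: str, fn: DetectorFn) -> None:
    """Register a detector callable ``image -> list[Detection]`` by name."""
    _REGISTRY[name] = fn


def get_detector(name: str) -> DetectorFn:
    if name == "baseline":
        return lambda image: detect_baseline(image)
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no detector {name!r}; registered: {['baseline', *_REGISTRY]}"
        ) from None
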