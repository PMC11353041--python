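"""End-to-end measurement: detections -> circle -> 3D position -> diameter.

For each detection the pipeline crops a padded ROI, runs the
preprocessing chain (grayscale, CLAHE, Gaussian blur, Canny), fits a
circle to the contour points by RANSAC with activation filtering, samples
the depth at the box centre, back-projects to camera coordinates, and
converts the fitted pixel radius to a metric diameter.  Failures on one
detection (no depth return, degenerate contour) are reported per record
and do not abort the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import camera, geometry, imaging
from .camera import Intrinsics, Point3D
from .detection import Detection
from .errors import (
    EmptyContourError,
    FitFailureError,
    FruitSizeError,
    InsufficientPointsError,
    InvalidDepthError,
)
from .geometry import Circle, FitResult, RansacConfig
from .imaging import PreprocessConfig

__all__ = ["MeasureOptions", "MeasurementRecord", "measure_detection", "measure_image"]

# ROI padding in pixels around each detection box.  A detector's tight box
# touches the silhouette, which would put the rim on the crop border where
# the edge detector cannot localise it; a small margin keeps the full
# contour interior to the ROI.
DEFAULT_ROI_PAD = 8


@dataclass(frozen=True)
class MeasureOptions:
    """Bundle of per-run pipeline settings."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    depth_mode: Literal["nearest", "median3"] = "nearest"
    focal_mode: Literal["mean", "fx", "fy"] = "mean"
    roi_pad: int = DEFAULT_ROI_PAD


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured detection; ``status`` is "ok" or the failure kind."""

    detection: Detection
    status: str
    circle: Circle | None = None          # full-image pixel coordinates
    fit: FitResult | None = None
    position: Point3D | None = None       # camera frame, metres
    diameter_mm: float | None = None
    message: str = ""


def measure_detection(
    image: np.ndarray,
    depth: np.ndarray,
    K: Intrinsics,
    det: Detection,
    options: MeasureOptions | None = None,
) -> MeasurementRecord:
    """Measure a single detection; never raises for per-fruit failures."""
    if options is None:
        options = MeasureOptions()
    try:
        roi = imaging.crop_roi(image, det.bbox.padded(options.roi_pad))
        gray = imaging.to_grayscale(roi.pixels)
        enhanced = imaging.enhance_contrast(gray, options.preprocess)
        blurred = imaging.smooth(enhanced, options.preprocess)
        edges = imaging.detect_edges(blurred, options.preprocess)
        points = imaging.extract_contour_points(edges)
        fit = geometry.ransac_circle(points, options.ransac)
    except EmptyContourError as exc:
        return MeasurementRecord(det, status="empty-contour", message=str(exc))
    except (FitFailureError, InsufficientPointsError) as exc:
        return MeasurementRecord(det, status="fit-failure", message=str(exc))

    circle = Circle(
        fit.circle.a + roi.x_offset, fit.circle.b + roi.y_offset, fit.circle.r
    )

    px, py = camera.bbox_center(det.bbox)
    try:
        z = camera.sample_depth(
            depth, px, py, mode=options.depth_mode, scale_mm=K.depth_scale
        )
        position = camera.backproject(px, py, z, K)
        diameter_mm = camera.pixel_radius_to_mm(circle.r, z, K, focal=options.focal_mode)
    except InvalidDepthError as exc:
        return MeasurementRecord(
            det, status="invalid-depth", circle=circle, fit=fit, message=str(exc)
        )

    return MeasurementRecord(
        det,
        status="ok",
        circle=circle,
        fit=fit,
        position=position,
        diameter_mm=diameter_mm,
    )


def measure_image(
    image: np.ndarray,
    depth: np.ndarray,
    K: Intrinsics,
    detections: Sequence[Detection],
    options: MeasureOptions | None = None,
) -> list[MeasurementRecord]:
    """Measure every detection in one frame."""
    return [measure_detection(image, depth, K, det, options) for det in detections]
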