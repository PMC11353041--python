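"""Accuracy statistics for frame-series diameter measurements.

A field evaluation compares, per fruit, a caliper-style reference
diameter against camera measurements collected over a sequence of frames
(typically 50).  Two summary statistics are reported per fruit:

* *deviation* — the absolute difference between the reference value and
  the series mean (the camera value);
* *dispersion* — the mean squared deviation of the per-frame
  measurements about the reference value, i.e. how much single-frame
  readings scatter around the true size.

Detection quality is summarised by the usual precision and recall
ratios computed from true/false positive and false negative counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptySeriesError, UndefinedRatioError

__all__ = [
    "MeasurementSeries",
    "AccuracyRecord",
    "series_mean",
    "deviation",
    "dispersion",
    "make_record",
    "error_range",
    "precision_recall",
]


@dataclass(frozen=True)
class MeasurementSeries:
    """Per-frame diameters (mm) of one fruit plus its reference value."""

    sample_id: str
    diameters_mm: tuple[float, ...]
    actual_mm: float

    def __post_init__(self) -> None:
        if len(self.diameters_mm) < 1:
            raise EmptySeriesError(f"{self.sample_id}: empty series")
        if self.actual_mm <= 0 or any(d <= 0 for d in self.diameters_mm):
            raise ValueError(f"{self.sample_id}: diameters must be positive")


@dataclass(frozen=True)
class AccuracyRecord:
    """One evaluation row: reference vs camera diameter and its scatter."""

    sample_id: str
    actual_mm: float
    camera_mm: float
    deviation_mm: float
    dispersion_mm2: float

    def __post_init__(self) -> None:
        if self.deviation_mm < 0:
            raise ValueError("deviation must be non-negative")


def series_mean(series: Sequence[float]) -> float:
    """Arithmetic mean of per-frame diameters (the camera value)."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise EmptySeriesError("empty measurement series")
    return float(arr.mean())


def deviation(actual_mm: float, camera_mm: float) -> float:
    """Absolute difference between reference and camera diameters."""
    if actual_mm <= 0 or camera_mm <= 0:
        raise ValueError("diameters must be positive")
    return abs(actual_mm - camera_mm)


def dispersion(series: Sequence[float], actual_mm: float) -> float:
    """Mean squared per-frame deviation about the reference diameter."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise EmptySeriesError("empty measurement series")
    return float(np.mean((arr - actual_mm) ** 2))


def make_record(series: MeasurementSeries) -> AccuracyRecord:
    """Full evaluation row for one measured fruit."""
    camera = series_mean(series.diameters_mm)
    return AccuracyRecord(
        sample_id=series.sample_id,
        actual_mm=series.actual_mm,
        camera_mm=camera,
        deviation_mm=deviation(series.actual_mm, camera),
        dispersion_mm2=dispersion(series.diameters_mm, series.actual_mm),
    )


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def error_range(records: Iterable[AccuracyRecord], decimals: int = 2) -> tuple[float, float]:
    """(min, max) of the per-fruit deviations, rounded half-up."""
    devs = [rec.deviation_mm for rec in records]
    if not devs:
        raise EmptySeriesError("no accuracy records")
    return (_round_half_up(min(devs), decimals), _round_half_up(max(devs), decimals))


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN).

    Raises :class:`UndefinedRatioError` when either denominator is zero.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise UndefinedRatioError("precision undefined: no predicted positives")
    precision = tp / (tp + fp)
    if tp + fn == 0:
        raise UndefinedRatioError("recall undefined: no actual positives")
    recall = tp / (tp + fn)
    return precision, recall
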