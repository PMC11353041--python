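"""ROI preprocessing and contour-point extraction.

The measurement chain runs per detection: crop the bounding box, convert
to grayscale, enhance local contrast (CLAHE), suppress noise with a
Gaussian blur, detect edges (Canny), and enumerate the edge pixels as an
unordered point cloud for the circle fitter.

Conventions: 0-based pixel coordinates, ``x`` = column, ``y`` = row,
half-open bounding boxes ``[xmin, xmax) x [ymin, ymax)``.  Contour points
are ROI-local; the crop records its offset so results can be mapped back
to full-image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.ndimage as ndi
from skimage import color, exposure, feature

from .errors import EmptyContourError, EmptyIntersectionError, ImageFormatError

__all__ = [
    "BBox",
    "PreprocessConfig",
    "Roi",
    "crop_roi",
    "to_grayscale",
    "enhance_contrast",
    "smooth",
    "detect_edges",
    "extract_contour_points",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, half-open: ``[xmin, xmax) x [ymin, ymax)``."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.xmin, self.ymin, self.xmax, self.ymax])):
            raise ValueError("bounding box coordinates must be finite")
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError(
                f"degenerate box: ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    def padded(self, pad: float) -> "BBox":
        """Box grown by ``pad`` pixels on every side."""
        return BBox(self.xmin - pad, self.ymin - pad, self.xmax + pad, self.ymax + pad)


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``clahe_clip_limit`` follows the common convention of a multiple of
    the mean tile-histogram height (2.0 is a standard mild setting); the
    tile grid splits the ROI into ``clahe_tile_grid x clahe_tile_grid``
    regions.  ``gaussian_sigma = 0`` derives the sigma from the kernel
    size with the usual ``0.3 * ((k - 1) / 2 - 1) + 0.8`` rule.  Canny
    hysteresis thresholds are expressed on a 0-255 scale *relative to the
    strongest gradient in the ROI*, which keeps edge extraction stable
    across the wide brightness range of field images.
    """

    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8
    gaussian_kernel: int = 5
    gaussian_sigma: float = 0.0
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.gaussian_kernel < 3 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 3")
        if not 0 < self.canny_low < self.canny_high:
            raise ValueError("require canny_high > canny_low > 0")
        if self.clahe_clip_limit <= 0 or self.clahe_tile_grid < 1:
            raise ValueError("invalid CLAHE parameters")

    @property
    def derived_sigma(self) -> float:
        if self.gaussian_sigma > 0:
            return self.gaussian_sigma
        k = self.gaussian_kernel
        return 0.3 * ((k - 1) * 0.5 - 1.0) + 0.8


class Roi(NamedTuple):
    """A cropped raster plus the offset of its origin in the full image."""

    pixels: np.ndarray
    x_offset: int
    y_offset: int


def _check_image(image: np.ndarray, channels: tuple[int, ...]) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 2:
        nchan = 1
    elif img.ndim == 3:
        nchan = img.shape[2]
    else:
        raise ImageFormatError(f"expected a 2D or 3D raster, got ndim={img.ndim}")
    if nchan == 4:
        raise ImageFormatError("alpha channel not supported; strip it explicitly")
    if nchan not in channels:
        raise ImageFormatError(f"expected {channels} channel(s), got {nchan}")
    if img.size == 0:
        raise ImageFormatError("empty image")
    return img


def crop_roi(image: np.ndarray, bbox: BBox) -> Roi:
    """Crop a bounding box from an image, clamping to the frame.

    Raises :class:`EmptyIntersectionError` when the box lies fully
    outside the image.
    """
    img = _check_image(image, channels=(1, 3))
    h, w = img.shape[:2]
    x0 = max(int(np.floor(bbox.xmin)), 0)
    y0 = max(int(np.floor(bbox.ymin)), 0)
    x1 = min(int(np.ceil(bbox.xmax)), w)
    y1 = min(int(np.ceil(bbox.ymax)), h)
    if x1 <= x0 or y1 <= y0:
        raise EmptyIntersectionError(
            f"box ({bbox.xmin}, {bbox.ymin}, {bbox.xmax}, {bbox.ymax}) "
            f"does not intersect a {w}x{h} image"
        )
    return Roi(img[y0:y1, x0:x1].copy(), x0, y0)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert RGB to 8-bit grayscale with standard luminance weights.

    Single-channel input passes through unchanged.
    """
    img = _check_image(image, channels=(1, 3))
    if img.ndim == 2:
        return img.copy()
    gray = color.rgb2gray(img)  # float in [0, 1]
    return np.clip(np.rint(gray * 255.0), 0, 255).astype(np.uint8)


def enhance_contrast(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation (CLAHE).

    A constant image has no contrast to amplify and is returned as-is.
    """
    if config is None:
        config = PreprocessConfig()
    img = _check_image(image, channels=(1,)).astype(np.uint8)
    if img.min() == img.max():
        return img.copy()
    h, w = img.shape
    kernel = (max(h // config.clahe_tile_grid, 1), max(w // config.clahe_tile_grid, 1))
    # clip limit: multiples of the mean bin height -> skimage's normalised scale
    clip = min(config.clahe_clip_limit / 256.0, 1.0)
    out = exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip)
    return np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)


def smooth(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Gaussian blur with a normalised kernel (mean-preserving)."""
    if config is None:
        config = PreprocessConfig()
    img = _check_image(image, channels=(1,)).astype(float)
    sigma = config.derived_sigma
    radius = (config.gaussian_kernel - 1) // 2
    out = ndi.gaussian_filter(img, sigma=sigma, truncate=radius / sigma, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def detect_edges(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Canny edge map of a grayscale image.

    Hysteresis thresholds are ``canny_low/255`` and ``canny_high/255`` of
    the strongest smoothed gradient magnitude in the ROI, so a clean
    step edge is found regardless of its absolute contrast and a
    constant image yields an empty map.
    """
    if config is None:
        config = PreprocessConfig()
    img = _check_image(image, channels=(1,)).astype(float)
    smoothed = ndi.gaussian_filter(img, config.canny_sigma)
    gx = ndi.sobel(smoothed, axis=1)
    gy = ndi.sobel(smoothed, axis=0)
    gmax = float(np.hypot(gx, gy).max())
    if gmax <= 0:
        return np.zeros(img.shape, dtype=bool)
    low = config.canny_low / 255.0 * gmax
    high = config.canny_high / 255.0 * gmax
    return feature.canny(
        img, sigma=config.canny_sigma, low_threshold=low, high_threshold=high
    )


def extract_contour_points(edges: np.ndarray) -> np.ndarray:
    """Edge pixels as an ``(n, 2)`` float array of ``(x, y)`` points.

    Points are ROI-local and emitted in raster-scan order (row-major).
    Raises :class:`EmptyContourError` on an empty map.
    """
    e = np.asarray(edges, dtype=bool)
    if e.ndim != 2:
        raise ImageFormatError("edge map must be 2D")
    rows, cols = np.nonzero(e)
    if rows.size == 0:
        raise EmptyContourError("no edge pixels in map")
    return np.column_stack([cols, rows]).astype(float)
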