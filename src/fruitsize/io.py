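"""Raster I/O: 8-bit RGB images and 16-bit depth maps as PNG."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ImageFormatError

__all__ = ["read_image", "write_image", "read_depth", "write_depth"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB (or grayscale) 8-bit raster from PNG/JPG."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        raise ImageFormatError(f"{path}: alpha channel not supported")
    if img.dtype != np.uint8:
        raise ImageFormatError(f"{path}: expected 8-bit pixels, got {img.dtype}")
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_depth(path: str | Path) -> np.ndarray:
    """Read a 16-bit depth raster (millimetres, 0 = invalid)."""
    depth = iio.imread(path)
    if depth.ndim != 2:
        raise ImageFormatError(f"{path}: depth raster must be single-channel")
    return depth.astype(np.uint16)


def write_depth(path: str | Path, depth: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(depth, dtype=np.uint16))
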