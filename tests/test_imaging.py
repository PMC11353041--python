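"""Preprocessing chain: crop, grayscale, CLAHE, blur, Canny, contours."""

import hashlib

import numpy as np
import pytest

from fruitsize.errors import EmptyContourError, EmptyIntersectionError, ImageFormatError
from fruitsize.geometry import RansacConfig, ransac_circle
from fruitsize.imaging import (
    BBox,
    PreprocessConfig,
    crop_roi,
    detect_edges,
    enhance_contrast,
    extract_contour_points,
    smooth,
    to_grayscale,
)

# frozen from the first verified run of enhance_contrast on
# default_rng(0).integers(0, 256, (64, 64)) — regression snapshot
_CLAHE_SNAPSHOT = "b18388f2ff82f3330526198669aaa44f248127b05d2165568d83d6f99b8f6eb8"


class TestCropRoi:
    def test_identity_crop(self):
        img = np.arange(100 * 100, dtype=np.uint8).reshape(100, 100)
        roi = crop_roi(img, BBox(0, 0, 100, 100))
        assert np.array_equal(roi.pixels, img)
        assert (roi.x_offset, roi.y_offset) == (0, 0)

    def test_half_open_dimensions(self):
        img = np.zeros((100, 100), dtype=np.uint8)
        roi = crop_roi(img, BBox(10, 20, 30, 60))
        assert roi.pixels.shape == (40, 20)
        assert (roi.x_offset, roi.y_offset) == (10, 20)

    def test_clamps_to_frame(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        roi = crop_roi(img, BBox(-10, -10, 20, 20))
        assert roi.pixels.shape == (20, 20)
        assert (roi.x_offset, roi.y_offset) == (0, 0)

    def test_outside_frame_rejected(self):
        img = np.zeros((50, 50), dtype=np.uint8)
        with pytest.raises(EmptyIntersectionError):
            crop_roi(img, BBox(100, 100, 120, 120))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BBox(10, 10, 10, 20)


class TestToGrayscale:
    def test_gray_input_unchanged(self):
        img = np.full((8, 8, 3), 200, dtype=np.uint8)
        assert np.unique(to_grayscale(img)).tolist() == [200]

    def test_primaries_distinct_and_in_range(self):
        red = to_grayscale(np.full((4, 4, 3), (255, 0, 0), dtype=np.uint8))
        blue = to_grayscale(np.full((4, 4, 3), (0, 0, 255), dtype=np.uint8))
        assert red[0, 0] != blue[0, 0]
        for g in (red, blue):
            assert 0 <= g.min() and g.max() <= 255

    def test_black_maps_to_zero(self):
        assert to_grayscale(np.zeros((4, 4, 3), dtype=np.uint8)).max() == 0

    def test_alpha_rejected(self):
        with pytest.raises(ImageFormatError):
            to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


class TestEnhanceContrast:
    def test_constant_image_unchanged(self):
        img = np.full((50, 50), 128, dtype=np.uint8)
        assert np.unique(enhance_contrast(img)).tolist() == [128]

    def test_two_level_separation_not_decreased(self):
        img = np.full((64, 64), 100, dtype=np.uint8)
        img[:, 32:] = 156
        out = enhance_contrast(img)
        sep_in = 156 - 100
        sep_out = int(out[:, 48:].mean()) - int(out[:, :16].mean())
        assert sep_out >= sep_in

    def test_regression_snapshot(self):
        img = np.random.default_rng(0).integers(0, 256, (64, 64), dtype=np.uint8)
        out = enhance_contrast(img)
        assert hashlib.sha256(out.tobytes()).hexdigest() == _CLAHE_SNAPSHOT


class TestSmooth:
    def test_constant_unchanged(self):
        img = np.full((30, 30), 77, dtype=np.uint8)
        assert np.array_equal(smooth(img), img)

    def test_impulse_mass_conserved(self):
        img = np.zeros((31, 31), dtype=np.uint8)
        img[15, 15] = 255
        out = smooth(img)
        assert out[15, 15] < 255  # mass spread out
        assert abs(int(out.sum()) - 255) <= 0.05 * 255 + 13  # rounding of ~13 taps

    def test_checkerboard_variance_reduced(self):
        img = np.indices((40, 40)).sum(axis=0) % 2 * 255
        out = smooth(img.astype(np.uint8))
        assert out.var() < img.var()

    def test_mean_preserved_within_one_level(self):
        img = np.random.default_rng(1).integers(0, 256, (60, 60)).astype(np.uint8)
        assert abs(float(smooth(img).mean()) - float(img.mean())) <= 1.0


class TestDetectEdges:
    def test_constant_image_no_edges(self):
        assert detect_edges(np.full((40, 40), 90, dtype=np.uint8)).sum() == 0

    def test_disk_edges_near_true_circle(self, disk_image):
        edges = detect_edges(smooth(disk_image))
        pts = extract_contour_points(edges)
        d = np.hypot(pts[:, 0] - 50, pts[:, 1] - 50)
        assert np.abs(d - 30).max() <= 2.0

    def test_step_edge_thin_vertical_line(self):
        img = np.full((40, 40), 50, dtype=np.uint8)
        img[:, 20:] = 200
        edges = detect_edges(img)
        cols = np.nonzero(edges)[1]
        assert cols.size > 0
        assert cols.max() - cols.min() <= 1  # <= 2 px thick


class TestExtractContourPoints:
    def test_empty_map_rejected(self):
        with pytest.raises(EmptyContourError):
            extract_contour_points(np.zeros((10, 10), dtype=bool))

    def test_exact_pixel_enumeration(self):
        edges = np.zeros((10, 10), dtype=bool)
        edges[2, 3] = edges[5, 7] = edges[9, 0] = True
        pts = extract_contour_points(edges)
        assert pts.tolist() == [[3, 2], [7, 5], [0, 9]]  # (x, y), raster order

    def test_disk_point_count_near_perimeter(self, disk_image):
        pts = extract_contour_points(detect_edges(smooth(disk_image)))
        assert abs(len(pts) - 2 * np.pi * 30) <= 0.2 * 2 * np.pi * 30


class TestPipelineGeometry:
    def test_full_chain_recovers_disk_radius(self, disk_image):
        """grayscale -> CLAHE -> blur -> Canny -> contours -> RANSAC stays
        within 1.5 px of the generating radius."""
        rgb = np.stack([disk_image] * 3, axis=-1)
        chain = smooth(enhance_contrast(to_grayscale(rgb)))
        pts = extract_contour_points(detect_edges(chain))
        res = ransac_circle(pts, RansacConfig(seed=5))
        assert abs(res.circle.r - 30) <= 1.5
        assert abs(res.circle.a - 50) <= 1.5
        assert abs(res.circle.b - 50) <= 1.5

    def test_stages_shape_preserving(self):
        img = np.random.default_rng(3).integers(0, 256, (37, 53)).astype(np.uint8)
        for stage in (enhance_contrast, smooth, detect_edges):
            assert stage(img).shape == img.shape

    def test_chain_deterministic(self):
        img = np.random.default_rng(4).integers(0, 256, (48, 48)).astype(np.uint8)
        a = extract_contour_points(detect_edges(smooth(enhance_contrast(img))))
        b = extract_contour_points(detect_edges(smooth(enhance_contrast(img))))
        assert np.array_equal(a, b)
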