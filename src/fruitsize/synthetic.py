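"""Ground-truth scene generation and augmentation operators.

Every stage of the sizing pipeline is testable without field data:
:func:`generate_scene` renders a near-circular fruit silhouette of known
centre, radius and depth over value-noise background clutter, optionally
with a partial occluder, sensor-style noise and brightness shifts, and
returns the paired depth raster plus an exact truth manifest.

The default conditions model a hand-sized red apple (80 mm diameter)
viewed by an RGB-D camera at arm's reach (0.8-1.5 m).  The default
intrinsics follow a RealSense-class colour sensor (focal length ~910 px
at 1280x720), rendered here as the central 640x480 crop of that frame.

The augmentation operators mirror a standard detector-training recipe:
Gaussian and salt-and-pepper noise, horizontal/vertical flips, histogram
equalisation, and brightness expansion, conventionally applied two at a
time.  :class:`DatasetManifest` carries the bookkeeping identities of
such a dataset (original + augmented = training + validation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, NamedTuple, Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import brentq
from skimage import exposure

from .camera import Intrinsics
from .errors import InvalidParamsError, UnknownOpError
from .geometry import Circle

__all__ = [
    "DEFAULT_INTRINSICS",
    "SceneParams",
    "SceneTruth",
    "DatasetManifest",
    "ManifestTotals",
    "generate_scene",
    "augment",
    "tally_manifest",
]

# RealSense-class colour sensor: ~910 px focal length at 1280x720; scenes
# are rendered as the central 640x480 crop of that frame.
DEFAULT_INTRINSICS = Intrinsics(
    ppx=319.5, ppy=239.5, fx=910.0, fy=910.0, width=640, height=480,
    depth_scale=1.0,
)

_FRUIT_COLOR = np.array([200.0, 55.0, 50.0])      # ripe red apple
_LEAF_COLOR = np.array([45.0, 70.0, 40.0])        # dark foliage
_SOIL_COLOR = np.array([70.0, 55.0, 35.0])        # branches / ground
_OCCLUDER_COLOR = np.array([90.0, 78.0, 60.0])    # gray-brown bark in front of fruit


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one rendered scene.

    The fruit size can be given either directly as ``radius_px`` or
    metrically as ``diameter_mm`` at depth ``z_m`` under ``intrinsics``
    (the pixel radius is then derived by the pinhole model).  Occlusion
    is the fraction of the fruit disk covered by the occluder and must
    stay below 0.5 — the fitting method assumes a mostly visible contour.
    """

    width: int = 640
    height: int = 480
    center: tuple[float, float] | None = None  # None: random, fully in frame
    radius_px: float | None = None
    diameter_mm: float = 80.0
    z_m: float = 1.0
    intrinsics: Intrinsics = DEFAULT_INTRINSICS
    axis_ratio: float = 1.0            # minor/major axis; >= 0.9
    occlusion: float = 0.0
    occluder_shape: Literal["rectangle", "ellipse"] = "rectangle"
    noise_sigma: float = 0.0           # additive Gaussian, 8-bit levels
    salt_pepper: float = 0.0           # fraction of pixels flipped
    brightness_offset: float = 0.0     # added to all channels
    depth_jitter_mm: float = 2.0       # sensor noise on the fruit surface
    seed: int = 0

    def derived_radius_px(self) -> float:
        if self.radius_px is not None:
            return float(self.radius_px)
        return (self.diameter_mm / 2.0 / 1000.0) * self.intrinsics.f_mean / self.z_m

    def validate(self) -> None:
        if self.width < 32 or self.height < 32:
            raise InvalidParamsError("scene must be at least 32x32")
        if self.z_m <= 0 or self.diameter_mm <= 0:
            raise InvalidParamsError("depth and diameter must be positive")
        r = self.derived_radius_px()
        if r < 5:
            raise InvalidParamsError(f"derived pixel radius {r:.2f} < 5")
        if 2 * r + 10 > min(self.width, self.height):
            raise InvalidParamsError("fruit does not fit in the frame")
        if not 0.0 <= self.occlusion < 0.5:
            raise InvalidParamsError("occlusion fraction must be in [0, 0.5)")
        if not 0.9 <= self.axis_ratio <= 1.0:
            raise InvalidParamsError("axis_ratio must be in [0.9, 1.0]")
        if not 0.0 <= self.salt_pepper < 1.0:
            raise InvalidParamsError("salt_pepper rate must be in [0, 1)")
        if self.noise_sigma < 0 or self.depth_jitter_mm < 0:
            raise InvalidParamsError("noise levels must be non-negative")
        if self.occluder_shape not in ("rectangle", "ellipse"):
            raise InvalidParamsError(f"unknown occluder shape {self.occluder_shape!r}")
        if self.center is not None:
            cx, cy = self.center
            if not (r <= cx <= self.width - r and r <= cy <= self.height - r):
                raise InvalidParamsError("fruit centre too close to the frame edge")


@dataclass(frozen=True)
class SceneTruth:
    """Exact ground truth recorded before any corruption is applied."""

    circle: Circle            # pixel-space silhouette circle
    diameter_mm: float
    z_m: float
    occlusion: float          # realised covered fraction of the disk
    seed: int

    def to_dict(self) -> dict:
        return {
            "center_x": self.circle.a,
            "center_y": self.circle.b,
            "radius_px": self.circle.r,
            "diameter_mm": self.diameter_mm,
            "z_m": self.z_m,
            "occlusion": self.occlusion,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SceneTruth":
        return cls(
            circle=Circle(data["center_x"], data["center_y"], data["radius_px"]),
            diameter_mm=data["diameter_mm"],
            z_m=data["z_m"],
            occlusion=data["occlusion"],
            seed=data["seed"],
        )


def _value_noise(rng: np.random.Generator, shape: tuple[int, int], cell: int) -> np.ndarray:
    """Smooth blotchy noise in [0, 1]: coarse random grid, cubic upsampling."""
    h, w = shape
    coarse = rng.random((h // cell + 2, w // cell + 2))
    zoomed = ndi.zoom(coarse, cell, order=3)[:h, :w]
    lo, hi = zoomed.min(), zoomed.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (zoomed - lo) / (hi - lo)


def _chord_offset(r: float, fraction: float) -> float:
    """Distance from centre to the chord whose circular segment covers
    the given area fraction of the disk."""
    if fraction <= 0:
        return r
    seg = lambda theta: (theta - np.sin(theta)) / (2.0 * np.pi) - fraction
    theta = brentq(seg, 1e-9, 2.0 * np.pi - 1e-9)
    return r * np.cos(theta / 2.0)


def generate_scene(params: SceneParams) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render one scene: RGB uint8 image, uint16 depth (mm), truth.

    Rendering is seed-deterministic; the truth circle and depth reflect
    the uncorrupted silhouette.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    r = params.derived_radius_px()
    K = params.intrinsics

    if params.center is None:
        margin = r + 8.0
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
    else:
        cx, cy = map(float, params.center)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # mildly elliptical silhouette: minor axis vertical, ratio >= 0.9
    dist = np.hypot(xx - cx, (yy - cy) / params.axis_ratio)
    coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)  # anti-aliased rim

    # background: foliage/soil mix with smooth blotches plus fine texture
    blotch = _value_noise(rng, (h, w), cell=40)
    texture = _value_noise(rng, (h, w), cell=8)
    bg = (_LEAF_COLOR[None, None] * blotch[..., None]
          + _SOIL_COLOR[None, None] * (1.0 - blotch[..., None]))
    bg = bg * (0.85 + 0.3 * texture[..., None])

    # fruit shading: brightest at the centre, Lambert-like falloff
    rel = np.clip(dist / r, 0.0, 1.0)
    shade = 0.85 + 0.15 * np.sqrt(np.clip(1.0 - rel * rel, 0.0, 1.0))
    fruit = _FRUIT_COLOR[None, None] * shade[..., None]

    img = bg * (1.0 - coverage[..., None]) + fruit * coverage[..., None]

    # depth raster: fruit at z, clutter behind, occluder in front
    z_mm = params.z_m * 1000.0
    depth = (z_mm + 800.0 + 400.0 * blotch).astype(float)
    fruit_px = coverage > 0.5
    depth[fruit_px] = z_mm + rng.normal(0.0, params.depth_jitter_mm, int(fruit_px.sum()))

    realised_occ = 0.0
    if params.occlusion > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(phi), np.sin(phi)])
        hoff = _chord_offset(r, params.occlusion)
        proj = (xx - cx) * u[0] + (yy - cy) * u[1]
        if params.occluder_shape == "rectangle":
            occ = proj >= hoff
        else:
            ecx = cx + (hoff + r) * u[0]
            ecy = cy + (hoff + r) * u[1]
            along = (xx - ecx) * u[0] + (yy - ecy) * u[1]
            across = -(xx - ecx) * u[1] + (yy - ecy) * u[0]
            occ = (along / r) ** 2 + (across / (1.6 * r)) ** 2 <= 1.0
        occ_tex = _value_noise(rng, (h, w), cell=12)
        img[occ] = _OCCLUDER_COLOR[None] * (0.8 + 0.4 * occ_tex[occ, None])
        depth[occ] = (params.z_m - 0.15) * 1000.0
        realised_occ = float((occ & fruit_px).sum() / max(fruit_px.sum(), 1))

    if params.brightness_offset:
        img = img + params.brightness_offset
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if params.salt_pepper > 0:
        flips = rng.random((h, w)) < params.salt_pepper
        values = rng.random((h, w)) < 0.5
        img[flips & values] = 255
        img[flips & ~values] = 0

    depth_u16 = np.clip(np.rint(depth), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    truth = SceneTruth(
        circle=Circle(cx, cy, r),
        diameter_mm=(params.diameter_mm if params.radius_px is None
                     else 2.0 * r * params.z_m * 1000.0 / K.f_mean),
        z_m=params.z_m,
        occlusion=realised_occ,
        seed=params.seed,
    )
    return img, depth_u16, truth


# ------------------------------------------------------------ augmentation

_AUGMENT_OPS = (
    "gaussian_noise", "salt_pepper", "h_flip", "v_flip", "hist_eq", "brightness",
)


def _apply_op(img: np.ndarray, name: str, opts: dict, rng: np.random.Generator) -> np.ndarray:
    if name == "gaussian_noise":
        sigma = float(opts.get("sigma", 10.0))
        if sigma == 0:
            return img
        noisy = img.astype(float) + rng.normal(0.0, sigma, img.shape)
        return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    if name == "salt_pepper":
        rate = float(opts.get("rate", 0.02))
        if rate == 0:
            return img
        out = img.copy()
        flips = rng.random(img.shape[:2]) < rate
        values = rng.random(img.shape[:2]) < 0.5
        out[flips & values] = 255
        out[flips & ~values] = 0
        return out
    if name == "h_flip":
        return img[:, ::-1].copy()
    if name == "v_flip":
        return img[::-1, :].copy()
    if name == "hist_eq":
        if img.ndim == 3:  # equalise channel-wise
            eq = np.stack(
                [exposure.equalize_hist(img[..., c]) for c in range(img.shape[2])],
                axis=-1,
            )
        else:
            eq = exposure.equalize_hist(img)
        return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    if name == "brightness":
        offset = float(opts.get("offset", 30.0))
        if offset == 0:
            return img
        out = img.astype(float) + offset
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    raise UnknownOpError(f"unknown augmentation op {name!r}; known: {_AUGMENT_OPS}")


def augment(
    image: np.ndarray,
    ops: Sequence[str | tuple[str, dict]],
    seed: int = 0,
) -> np.ndarray:
    """Apply augmentation ops in order; deterministic for a given seed.

    Each op is a name or ``(name, options)`` pair.  The conventional
    training recipe combines exactly two ops per augmented copy, but any
    non-empty sequence is accepted.
    """
    if len(ops) == 0:
        raise ValueError("need at least one augmentation op")
    img = np.asarray(image)
    if img.dtype != np.uint8:
        raise ValueError("augment expects an 8-bit image")
    rng = np.random.default_rng(seed)
    out = img.copy()
    for op in ops:
        name, opts = (op, {}) if isinstance(op, str) else op
        out = _apply_op(out, name, opts, rng)
    return out


# ------------------------------------------------------------- accounting


@dataclass(frozen=True)
class DatasetManifest:
    """Per-class image counts of a split-then-augment training dataset."""

    label: str = "goodapple"
    original: int = 0
    augmented: int = 0
    training: int = 0
    validation: int = 0

    def __post_init__(self) -> None:
        for name in ("original", "augmented", "training", "validation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be non-negative")


class ManifestTotals(NamedTuple):
    total_images: int      # original + augmented
    total_split: int       # training + validation
    consistent: bool


def tally_manifest(manifest: DatasetManifest) -> ManifestTotals:
    """Totals and the bookkeeping identity original+augmented == training+validation."""
    total_images = manifest.original + manifest.augmented
    total_split = manifest.training + manifest.validation
    return ManifestTotals(total_images, total_split, total_images == total_split)
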