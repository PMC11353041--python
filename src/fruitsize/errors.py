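"""Exception hierarchy for the fruitsize package.

Every error raised by the library derives from :class:`FruitSizeError` so
callers can catch the whole family with a single clause; the CLI maps the
subclasses onto stable exit codes.
"""


class FruitSizeError(Exception):
    """Base class for all fruitsize errors."""


# ---------------------------------------------------------------- geometry
class InsufficientPointsError(FruitSizeError):
    """Fewer points than the minimum required to determine a circle."""


class DegenerateSampleError(FruitSizeError):
    """A 3-point sample is collinear or contains duplicates."""


class DegenerateConfigurationError(FruitSizeError):
    """A point set admits no unique least-squares circle (e.g. collinear)."""


class FitFailureError(FruitSizeError):
    """No valid circle model could be produced from the data."""


# ----------------------------------------------------------------- imaging
class EmptyIntersectionError(FruitSizeError):
    """A bounding box does not overlap the image at all."""


class ImageFormatError(FruitSizeError):
    """Unsupported raster layout (wrong channel count, alpha present...)."""


class EmptyContourError(FruitSizeError):
    """An edge map contains no set pixels."""


# ------------------------------------------------------------------ camera
class InvalidDepthError(FruitSizeError):
    """Depth unavailable (sensor dropout) or non-positive where required."""


class NonPositiveInputError(FruitSizeError):
    """A strictly positive quantity (radius, depth) was zero or negative."""


class ShortSeriesError(FruitSizeError):
    """A frame series is shorter than the averaging window."""


# -------------------------------------------------------------- evaluation
class EmptySeriesError(FruitSizeError):
    """A measurement series contains no frames."""


class UndefinedRatioError(FruitSizeError):
    """Precision or recall requested with a zero denominator."""


# --------------------------------------------------------------- synthetic
class InvalidParamsError(FruitSizeError):
    """Scene parameters violate their invariants."""


class UnknownOpError(FruitSizeError):
    """An augmentation op name is not recognised."""


# ----------------------------------------------------------- detection/cli
class DetectionParseError(FruitSizeError):
    """A detections file is malformed; message carries the row number."""


class JoinMismatchError(FruitSizeError):
    """Sample ids in results and reference files do not line up."""


class ConfigError(FruitSizeError):
    """A run configuration contains unknown keys or invalid values."""
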