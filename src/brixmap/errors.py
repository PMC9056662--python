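"""Exception hierarchy.

Every error raised by the package derives from :class:`BrixmapError` so
callers can catch pipeline failures with one handler while still
distinguishing stages.
"""


class BrixmapError(Exception):
    """Base class for all package errors."""


class ConfigError(BrixmapError, ValueError):
    """Invalid configuration; the message names the offending field."""


class FormatError(BrixmapError, ValueError):
    """Malformed or contradictory ENVI header / serialized artifact."""


class CalibrationError(BrixmapError, ValueError):
    """Reflectance calibration impossible (white <= dark somewhere)."""


class ExtractionError(BrixmapError, ValueError):
    """ROI spectrum extraction failed (e.g. empty ROI)."""


class GeometryError(BrixmapError, ValueError):
    """Synthetic disc layout cannot be realized."""


class TransformError(BrixmapError, ValueError):
    """A spectral pretreatment could not be applied to a row."""


class FitError(BrixmapError, ValueError):
    """Model fitting failed (degenerate response, rank deficiency...)."""


class CoverageError(BrixmapError, RuntimeError):
    """A Monte Carlo procedure left some sample never predicted."""


class ThresholdError(BrixmapError, ValueError):
    """Automatic outlier thresholding on a degenerate distribution."""


class PartitionError(BrixmapError, ValueError):
    """Sample-set partitioning impossible (e.g. all-identical samples)."""


class SelectionError(BrixmapError, ValueError):
    """Wavelength selection failed for every candidate."""


class MappingError(BrixmapError, ValueError):
    """Pixel-wise prediction could not be applied to a cube."""


class SegmentationError(BrixmapError, ValueError):
    """Foreground segmentation produced an empty mask."""


class RenderError(BrixmapError, ValueError):
    """Pseudo-color rendering with a degenerate value range."""
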