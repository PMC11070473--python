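"""Exception hierarchy for the stem-diameter pipeline.

Every stage raises a subclass of :class:`StemDepthError`, so callers can
catch pipeline failures without masking programming errors.
"""


class StemDepthError(Exception):
    """Base class for all pipeline errors."""


class InvalidDepthError(StemDepthError):
    """Depth value is zero/negative where a positive depth is required."""


class BoundsError(StemDepthError):
    """Pixel coordinate outside the image raster."""


class BehindCameraError(StemDepthError):
    """Attempted to project a point with non-positive Z."""


class FrameMismatchError(StemDepthError):
    """3-D points tagged with incompatible coordinate frames."""


class ShapeError(StemDepthError):
    """Raster dimensions disagree with the camera model or each other."""


class EmptyMaskError(StemDepthError):
    """A binary mask required to be non-empty contains no foreground."""


class EmptyRoiError(StemDepthError):
    """No skeleton pixel falls inside the requested region of interest."""


class OpenContourError(StemDepthError):
    """A scanline failed to intersect the stem contour on both sides."""


class NoDepthError(StemDepthError):
    """No valid depth available at or around a measurement point."""


class MeasurementFailedError(StemDepthError):
    """Every scanline of a stem measurement failed."""

    def __init__(self, message, reasons=None):
        super().__init__(message)
        #: per-scanline failure descriptions, for diagnostics
        self.reasons = reasons or []


class GeometryError(StemDepthError):
    """Synthetic scene geometry is inconsistent (e.g. stem out of frustum)."""


class ConvergenceError(StemDepthError):
    """Iterative thinning failed to reach a fixed point within max_iter."""


class ParameterError(StemDepthError):
    """A parameter is out of its valid range (kernel size, scale factor...)."""


class FormatError(StemDepthError):
    """A file on disk does not match the declared format."""
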