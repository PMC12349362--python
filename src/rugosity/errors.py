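"""Exception and warning hierarchy for the rugosity package."""


class RugosityError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RugosityError, ValueError):
    """A numeric parameter is non-finite or outside its allowed range."""


class InvalidContourError(RugosityError, ValueError):
    """A polyline does not satisfy the contour contract (n >= 2, finite, distinct)."""


class RenderError(RugosityError, ValueError):
    """A contour cannot be rasterised (e.g. not graph-like on the pixel grid)."""


class DegenerateImageError(RugosityError, ValueError):
    """An image is all-foreground or all-background after thresholding."""


class BrokenBoundaryError(RugosityError, ValueError):
    """The traced boundary has a gap wider than the configured maximum."""


class DegenerateDesignError(RugosityError, ValueError):
    """A regression or test design has no usable variance."""


class InsufficientReplicationError(RugosityError, ValueError):
    """A group comparison was requested with fewer than two observations per group."""


class DegenerateSampleError(RugosityError, ValueError):
    """A sample column is unusable (e.g. zero total counts)."""


class UndefinedRatioError(RugosityError, ValueError):
    """A ratio of group means has a zero denominator."""


class MeasurementWarning(UserWarning):
    """Non-fatal measurement anomaly (e.g. epidermal length below section length)."""
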