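"""Exception hierarchy shared across the package."""


class WBCDetectError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(WBCDetectError, ValueError):
    """Malformed input (non-finite intensities, bad bounds, bad parameters)."""


class DegenerateInputError(WBCDetectError, ValueError):
    """Input admits no meaningful answer (e.g. constant image for a mixture)."""


class TooFewEdgesError(WBCDetectError, ValueError):
    """Fewer than five edge pixels: no ellipse candidate can be formed."""


class DegenerateCandidateError(WBCDetectError, ValueError):
    """Five points do not determine a unique conic (collinear/duplicate/ill-conditioned)."""


class NonEllipseError(WBCDetectError, ValueError):
    """Conic coefficients describe a hyperbola, parabola or degenerate conic."""


class TooSmallError(WBCDetectError, ValueError):
    """Ellipse axes below the one-pixel rasterization minimum."""


class UndefinedMetricError(WBCDetectError, ZeroDivisionError):
    """Metric denominator is zero (no expert-counted objects)."""
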