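"""Exception types shared across the pipeline stages."""


class PicscanError(Exception):
    """Base class for all picscan errors."""


class ValidationError(PicscanError, ValueError):
    """Invalid configuration or argument values."""


class ConfigurationError(PicscanError):
    """A required channel, marker or config entry is missing."""


class PlacementError(PicscanError):
    """An object or pair could not be placed on the canvas within the retry budget."""


class GeometryError(PicscanError):
    """Masks or rasters violate a geometric precondition."""


class InsufficientDataError(PicscanError):
    """Too few events to compute the requested statistic."""


class DegenerateDistributionError(PicscanError):
    """Zero-variance intensity distribution; an SD-based threshold is undefined."""


class DegenerateContactError(PicscanError):
    """Perimeter is entirely contact or entirely non-contact; fold change undefined."""


class UndefinedRatioError(PicscanError):
    """Denominator of a ratio is (numerically) zero."""
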