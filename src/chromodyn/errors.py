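"""Exception hierarchy for chromodyn.

All package-specific failures derive from :class:`ChromodynError` so callers
can catch one base class at pipeline level.
"""


class ChromodynError(Exception):
    """Base class for all chromodyn errors."""


class InvalidScheduleError(ChromodynError, ValueError):
    """Acquisition schedule has non-positive intervals or negative counts."""


class ParameterError(ChromodynError, ValueError):
    """A numeric parameter is outside its valid range."""


class GeometryError(ChromodynError, ValueError):
    """An ROI or mask does not intersect the frame/nucleus as required."""


class InsufficientRegionError(ChromodynError, ValueError):
    """Analysis mask has too few pixels for a meaningful correlation."""


class NormalizationError(ChromodynError, ValueError):
    """A normalization reference (mean or maximum) is zero or negative."""


class ConfigError(ChromodynError, ValueError):
    """Pipeline configuration is incomplete or inconsistent."""
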