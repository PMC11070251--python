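"""Exception hierarchy shared across the pipeline stages."""

__all__ = [
    "MoonchorusError",
    "ConfigError",
    "FormatError",
    "ParameterError",
    "EphemerisError",
    "JoinError",
    "ModelError",
    "ComparisonError",
    "PlacementError",
]


class MoonchorusError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(MoonchorusError, ValueError):
    """Invalid site, schedule or pipeline configuration."""


class FormatError(MoonchorusError, ValueError):
    """Malformed input file (missing column, inverted interval, ...)."""


class ParameterError(MoonchorusError, ValueError):
    """Invalid numerical parameter to an operation."""


class EphemerisError(MoonchorusError, ValueError):
    """Timestamp outside the supported ephemeris range."""


class JoinError(MoonchorusError, KeyError):
    """A record references a site with no configuration."""


class ModelError(MoonchorusError, ValueError):
    """Model specification cannot be fitted to the given records."""


class ComparisonError(MoonchorusError, ValueError):
    """Fits being compared are not on the same data."""


class PlacementError(MoonchorusError, ValueError):
    """A record falls outside the recording schedule."""
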