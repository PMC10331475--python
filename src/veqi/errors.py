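"""Typed exceptions shared across the package."""


class VeqiError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VeqiError):
    """Invalid or inconsistent configuration values."""


class ShapeError(VeqiError):
    """Grids that must be co-registered do not share a shape."""


class DomainError(VeqiError):
    """An input falls outside the mathematical domain of an operation."""


class SampleSizeError(VeqiError):
    """A series or table is too short for the requested statistic."""


class MissingDataError(VeqiError):
    """NaN encountered where the operation requires complete data."""


class DegenerateIndicatorError(VeqiError):
    """An indicator is constant and carries no information to weight."""


class DependencyError(VeqiError):
    """A pipeline stage's required upstream output is missing."""


class IOFormatError(VeqiError):
    """A raster file is unreadable or has the wrong dimensions."""
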