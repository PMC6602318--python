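"""Exception types shared across the package."""


class CircafishError(Exception):
    """Base class for all package errors."""


class FormatError(CircafishError):
    """A file could not be parsed as one of the supported formats."""


class EmptyInputError(CircafishError):
    """An operation received an empty sequence where data is required."""


class ConfigError(CircafishError):
    """Invalid configuration (layout, schedule, thresholds)."""


class DimensionError(CircafishError):
    """Mismatched array shapes."""


class DegenerateNormalizationError(CircafishError):
    """Min-max normalization of a constant series is undefined."""


class InsufficientDataError(CircafishError):
    """Not enough samples to carry out a statistical comparison."""


class UndefinedCorrelationError(CircafishError):
    """Correlation of a constant series is undefined."""


class RenderError(CircafishError):
    """A trajectory cannot be rendered inside the frame."""
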