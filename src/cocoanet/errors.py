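"""Exception hierarchy shared across the package."""


class CocoanetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CocoanetError):
    """A file or table does not have the expected layout."""


class ValidationError(CocoanetError):
    """Data violates a contract (negative peaks, missing labels, ...)."""


class ConfigurationError(CocoanetError):
    """An invalid generator or pipeline configuration."""


class DegenerateVarianceError(ValidationError):
    """A sample profile is constant, so its correlation is undefined."""


class UndefinedValueError(CocoanetError):
    """A statistic has an empty denominator (e.g. similarity of an edgeless
    network). Callers that can represent the undefined state should catch
    this and emit an explicit null instead."""
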