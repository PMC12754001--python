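"""Typed exceptions shared across the package."""


class CTIQAError(Exception):
    """Base class for all package errors."""


class ValidationError(CTIQAError, ValueError):
    """Input violates a documented precondition."""


class FormatError(CTIQAError, ValueError):
    """A file or serialized object is malformed or of the wrong layout."""


class ConfigError(CTIQAError, ValueError):
    """A configuration object is inconsistent or unsupported."""


class UndefinedMetricError(CTIQAError, ValueError):
    """A metric is mathematically undefined for the given input
    (e.g. a correlation of a constant vector)."""
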