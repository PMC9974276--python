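"""Exception hierarchy shared across the pipeline stages."""


class MslesionError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MslesionError, ValueError):
    """An invalid configuration object or parameter combination."""


class DimensionError(MslesionError, ValueError):
    """Mismatched or unsupported array dimensions."""


class DataValidationError(MslesionError, ValueError):
    """Input data violates a precondition (e.g. a single-class label vector)."""


class FormatError(MslesionError, ValueError):
    """A file is not in the expected format."""


class DependencyError(MslesionError, ImportError):
    """An optional dependency needed for the requested backend is missing."""
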