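"""Exception hierarchy shared across the package."""


class AluEditError(Exception):
    """Base class for all package errors."""


class FormatError(AluEditError, ValueError):
    """A file on disk violates its declared format."""


class ValidationError(AluEditError, ValueError):
    """An in-memory value violates a documented invariant."""


class ConfigurationError(AluEditError, ValueError):
    """An unknown or inconsistent configuration value."""


class SizingError(AluEditError, ValueError):
    """Requested simulated features do not fit in the configured space."""
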