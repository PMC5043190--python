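"""Exception types shared across the package."""


class MemovieError(Exception):
    """Base class for package errors."""


class ConfigurationError(MemovieError):
    """A configuration value is invalid or references unknown entities."""


class DataIntegrityError(MemovieError):
    """A dataset violates its referential-integrity contract."""


class DatasetValidationError(MemovieError):
    """A loaded table fails schema or invariant validation."""
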