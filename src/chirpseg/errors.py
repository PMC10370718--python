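"""Exception hierarchy shared across the package."""


class ChirpsegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChirpsegError, ValueError):
    """File content does not match the expected format."""


class MissingColumnError(FormatError):
    """A required column is absent from a selection table."""


class ConflictError(ChirpsegError, ValueError):
    """Overlapping annotations of different non-background classes."""


class ParameterError(ChirpsegError, ValueError):
    """A configuration value is outside its legal range."""


class InputError(ChirpsegError, ValueError):
    """A data input violates a precondition (empty, too short, ...)."""


class ShapeError(ChirpsegError, ValueError):
    """Array shapes of two arguments do not agree."""


class ConfigError(ChirpsegError, ValueError):
    """A configuration file or section is invalid."""
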