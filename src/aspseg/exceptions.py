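"""Exception hierarchy used across the package."""


class AspsegError(Exception):
    """Base class for all package errors."""


class DimensionError(AspsegError, ValueError):
    """Mask shapes disagree or an image is too small for the operation."""


class DomainError(AspsegError, ValueError):
    """A value lies outside its mathematical domain (e.g. probability > 1)."""


class ConfigError(AspsegError, ValueError):
    """An invalid hyperparameter or configuration."""


class DataError(AspsegError, ValueError):
    """Malformed or inconsistent input data (empty lists, length mismatch)."""


class StateError(AspsegError, RuntimeError):
    """An operation was called before its prerequisite state existed."""


class NumericalError(AspsegError, ArithmeticError):
    """A numerical computation failed despite regularization."""
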