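"""Exception hierarchy shared across the package."""


class CycleageError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CycleageError, ValueError):
    """A configuration object failed validation; the message names the field."""


class InputError(CycleageError, ValueError):
    """Input data violate an operation's preconditions."""


class ParameterError(CycleageError, ValueError):
    """An operation parameter is outside its admissible range."""


class ParseError(CycleageError, ValueError):
    """A file could not be parsed; the message carries row/column context."""


class ComputationError(CycleageError, RuntimeError):
    """A result is undefined for the given data (e.g. no luminal cells)."""
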