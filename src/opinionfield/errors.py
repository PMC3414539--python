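"""Exception types shared across the package."""


class OpinionFieldError(Exception):
    """Base class for all package errors."""


class ConfigError(OpinionFieldError, ValueError):
    """Invalid simulation configuration (bad sizes, probabilities, keys)."""


class LogicError(OpinionFieldError, RuntimeError):
    """An operation was called in a state where it is not defined."""


class SolverError(OpinionFieldError, RuntimeError):
    """The mean-field solver could not find an admissible solution."""


class ValidationError(OpinionFieldError, ValueError):
    """Survey table failed schema validation."""
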