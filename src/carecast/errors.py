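"""Exception hierarchy for carecast."""


class CarecastError(Exception):
    """Base class for all carecast errors."""


class IntegrityError(CarecastError):
    """A bundled or user-supplied data table violates a structural invariant."""


class EstimationError(CarecastError):
    """An estimator could not produce a valid result (empty cell, non-convergence)."""


class ConfigurationError(CarecastError):
    """A configuration value is missing or inconsistent."""


class ParseError(CarecastError):
    """A file could not be parsed; carries the offending line where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
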