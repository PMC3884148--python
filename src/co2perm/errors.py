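"""Package-wide exception types."""


class CO2PermError(Exception):
    """Base class for all co2perm errors."""


class InvalidInputError(ValueError, CO2PermError):
    """A physically or structurally invalid input (non-positive thickness, ...)."""


class ConvergenceError(RuntimeError, CO2PermError):
    """A numerical procedure failed to converge; carries a residual report."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class MetricError(CO2PermError):
    """A trace metric could not be computed (e.g. non-monotone trace)."""


class ParseError(CO2PermError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class ConfigError(CO2PermError):
    """Invalid run configuration; message names the offending key."""
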