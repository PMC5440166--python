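"""Exception hierarchy shared across the package."""


class ElkVdpError(Exception):
    """Base class for package errors."""


class InvalidInputError(ElkVdpError, ValueError):
    """A caller supplied data that violates an operation's preconditions."""


class ConfigError(ElkVdpError, ValueError):
    """A scheme/protocol/run configuration is malformed or inconsistent."""


class ParseError(ElkVdpError, ValueError):
    """A delimited-text input file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FitError(ElkVdpError, RuntimeError):
    """A nonlinear least-squares fit failed to converge."""


class UnreliableFitWarning(UserWarning):
    """A fit converged but its parameters should not be trusted."""
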