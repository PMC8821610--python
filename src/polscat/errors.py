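"""Exception hierarchy.

``ValidationError`` marks bad input (CLI exit code 2); ``ComputationError``
marks a numerical failure (CLI exit code 1).
"""


class PolscatError(Exception):
    """Base class for all package errors."""


class ValidationError(PolscatError, ValueError):
    """Invalid user input: bad file, bad parameters, empty structure."""


class ParseError(ValidationError):
    """A structure file could not be parsed."""


class ComputationError(PolscatError, RuntimeError):
    """A numerical procedure failed (non-convergence, singular system)."""


class ConvergenceError(ComputationError):
    """Iterative solver did not reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class DegenerateStatesError(ValidationError):
    """Two states are indistinguishable: the resolving intensity diverges."""
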