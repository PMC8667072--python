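"""Exception hierarchy.

``ValidationError`` covers malformed inputs and contract violations
(CLI exit code 2); ``ConvergenceError`` covers iterative solves that
fail to reach tolerance (CLI exit code 3).
"""


class RwrScreenError(Exception):
    """Base class for all package errors."""


class ValidationError(RwrScreenError, ValueError):
    """Invalid input data, parameters, or file contents."""


class ParseError(ValidationError):
    """Malformed input file; message names the offending line."""


class ConvergenceError(RwrScreenError, RuntimeError):
    """Iterative solver did not converge within the iteration budget."""

    def __init__(self, message: str, last_change: float | None = None):
        super().__init__(message)
        self.last_change = last_change
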