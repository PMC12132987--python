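"""Exception hierarchy.

``DataError`` (and subclasses) map to CLI exit code 2,
``ConvergenceError`` to exit code 3.
"""


class BNTError(Exception):
    """Base class for all package errors."""


class DataError(BNTError, ValueError):
    """Invalid or unusable input data."""


class DimensionError(DataError):
    """Shape mismatch between coefficient vectors and design matrices."""

    def __init__(self, what: str, expected, actual):
        super().__init__(f"{what}: expected {expected}, got {actual}")
        self.expected = expected
        self.actual = actual


class DegenerateDataError(DataError):
    """Data that makes the requested fit ill-posed (single outcome class,
    constant covariate, too few positive rows, ...)."""


class ConvergenceError(BNTError, RuntimeError):
    """An iterative fit failed to converge; carries the iteration trace
    when one is available (``.trace``)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
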