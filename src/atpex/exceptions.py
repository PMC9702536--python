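"""Exception hierarchy shared across the toolkit.

All errors raised by atpex derive from :class:`AtpexError` so callers can
catch the whole family with one clause; the leaf classes also inherit from
the closest builtin (``ValueError`` for bad inputs, ``RuntimeError`` for
numerical failures) to stay idiomatic.
"""


class AtpexError(Exception):
    """Base class for all atpex errors."""


class DomainError(AtpexError, ValueError):
    """An input lies outside the physical or mathematical domain."""


class InsufficientDataError(AtpexError, ValueError):
    """Too few data points to determine the model parameters."""


class DegenerateDataError(AtpexError, ValueError):
    """Data carry no usable signal (e.g. all-zero yields, flat objective)."""


class SingularDesignError(AtpexError, ValueError):
    """Regression design matrix is rank deficient."""


class ConvergenceError(AtpexError, RuntimeError):
    """An iterative solver or optimizer failed to converge.

    ``fallback`` may carry a usable lower-fidelity result (e.g. the
    log-linear binodal fit when the nonlinear refinement diverges).
    """

    def __init__(self, message: str, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class TrainingError(AtpexError, RuntimeError):
    """Neural-network training failed (non-finite loss or no candidate converged)."""


class SchemaError(AtpexError, ValueError):
    """A tabular input file does not match the expected column schema."""


class ParseError(AtpexError, ValueError):
    """A file exists but a cell or field cannot be parsed."""


class ValidationError(AtpexError, ValueError):
    """Parsed records violate a type invariant (with row context)."""
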