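"""Exception hierarchy shared across the package."""


class FractalSADError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FractalSADError, ValueError):
    """A scalar argument violates its precondition (S < 1, A1 <= 0, a < 0, ...)."""


class InvalidSampleError(FractalSADError, ValueError):
    """A rank-abundance vector is malformed (non-positive or unsorted abundances)."""


class InsufficientRanksError(InvalidSampleError):
    """Fewer than two ranks: the exponent estimator's denominator would be zero."""


class DivergentSeriesError(FractalSADError, ArithmeticError):
    """The generalized harmonic series diverges for the requested exponent (p <= 1).

    This is a contract, not a numerical failure: the infinite-richness effective
    species number simply does not exist below the convergence boundary.
    """


class InvalidSpecError(FractalSADError, ValueError):
    """A synthetic-community specification is inconsistent or incomplete."""


class DialectError(FractalSADError, ValueError):
    """An abundance table does not match the declared column dialect."""


class InvalidRecordError(FractalSADError, ValueError):
    """A data row is unusable (negative or unparseable abundance)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class EmptyInputError(FractalSADError, ValueError):
    """An operation requiring at least one element received none."""
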