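"""Exception hierarchy shared across the package."""


class SMTError(Exception):
    """Base class for all package errors."""


class TrackFormatError(SMTError):
    """A track or outline table is malformed (e.g. a required column is missing)."""


class TrackValidationError(SMTError):
    """Table content violates a track invariant (duplicate or non-monotone frames)."""


class ArgumentError(SMTError, ValueError):
    """An operation received an invalid argument."""


class EmptySampleError(SMTError):
    """No data survived extraction / filtering."""


class SampleSizeError(SMTError):
    """Sample too small for the requested fit."""


class DegenerateInputError(SMTError):
    """Input is degenerate for the requested computation (e.g. all-zero counts)."""


class ConvergenceError(SMTError):
    """An iterative fit did not converge within its iteration budget.

    Carries the last iterate in ``last_fit`` so callers can inspect it.
    """

    def __init__(self, message: str, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit
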