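"""Exception types shared across the pipeline."""


class YieldPathError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(YieldPathError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(YieldPathError, ValueError):
    """Too few observations to attempt an estimate."""


class NotPSDError(YieldPathError, ValueError):
    """A matrix required to be positive semidefinite is not."""

    def __init__(self, message: str, min_eigenvalue: float | None = None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class CoverageError(YieldPathError, ValueError):
    """A requested window is not covered by the supplied series."""


class DegenerateDataError(YieldPathError, ValueError):
    """Data carry no information for the requested estimate."""


class CollinearityError(YieldPathError, ValueError):
    """A design or predictor set is rank deficient."""


class InvalidPhenologyError(YieldPathError, ValueError):
    """Reproductive-stage dates violate their ordering."""
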