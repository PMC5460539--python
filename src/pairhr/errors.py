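"""Exception hierarchy shared across the package.

Validation problems (bad records, malformed files, bad configuration) and
numerical/boundary problems (estimates diverging, non-convergence) are kept
on separate branches so callers — in particular the command line — can map
them to distinct exit codes.
"""


class PairHRError(Exception):
    """Base class for all package errors."""


class ValidationError(PairHRError):
    """Invalid input data or configuration."""


class InvalidRecordError(ValidationError):
    """A subject or pair record violates its invariants."""


class PairingError(ValidationError):
    """Long-format data whose pairs are not one exposed + one unexposed."""


class ConfigError(ValidationError):
    """Invalid simulation or run configuration."""


class NumericalError(PairHRError):
    """Estimation failed for numerical reasons."""


class BoundaryError(NumericalError):
    """The estimate lies on the boundary of the parameter space.

    ``direction`` is ``'+inf'`` or ``'-inf'`` (or ``'0'``) describing where
    the point estimate diverges.
    """

    def __init__(self, message: str, direction: str | None = None):
        super().__init__(message)
        self.direction = direction


class NoInformationError(NumericalError):
    """No comparable pairs / no events: the data carry no information."""


class ConvergenceError(NumericalError):
    """Iterative maximization did not converge within the allowed steps."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SeparationError(NumericalError):
    """Monotone likelihood: a coefficient diverges (perfect separation)."""


class RankError(NumericalError):
    """Singular information matrix / rank-deficient design."""
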