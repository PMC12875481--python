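"""Exception hierarchy for ineqddm."""


class IneqDDMError(Exception):
    """Base class for all package errors."""


class InvalidOfferError(IneqDDMError):
    """An offer violates the task design (negative yen, jitter out of range)."""


class TrialParseError(IneqDDMError):
    """A trial table could not be parsed; message names the offending rows."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class DiagnosticsError(IneqDDMError):
    """Design diagnostics could not be computed (e.g. zero-variance regressor)."""


class SpecMismatchError(IneqDDMError):
    """Drift spec and parameter set do not match."""


class NoDataError(IneqDDMError):
    """No valid (non-timeout) trials available for fitting."""


class InsufficientChainsError(IneqDDMError):
    """Convergence diagnostics need at least two chains."""


class InsufficientDataError(IneqDDMError):
    """Too few trials for the requested fit."""


class AlignmentError(IneqDDMError):
    """Participant or trial sets do not line up across inputs."""


class NormalizationError(IneqDDMError):
    """Response-time normalization impossible (no equal-split trials)."""


class ConfigError(IneqDDMError):
    """Invalid configuration."""
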