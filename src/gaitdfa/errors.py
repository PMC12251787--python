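"""Exception hierarchy used across the package."""


class GaitDfaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GaitDfaError):
    """A file or record violates the expected on-disk layout."""


class RoleResolutionError(GaitDfaError):
    """Channel names could not be mapped to channel roles."""

    def __init__(self, message, unmatched=()):
        super().__init__(message)
        self.unmatched = tuple(unmatched)


class DegenerateSignalError(GaitDfaError):
    """Signal is constant / all-zero where variation is required."""


class TooShortError(GaitDfaError):
    """Series too short for the requested operation."""


class InvalidCutoffError(GaitDfaError):
    """Filter cutoff incompatible with the sampling rate."""


class WindowTooSmallError(GaitDfaError):
    """DFA window size below the minimum usable size."""


class InsufficientScalesError(GaitDfaError):
    """Fewer usable window sizes than required for a log-log fit."""


class NoCycleError(GaitDfaError):
    """Fewer than two heel strikes: no gait cycle can be formed."""


class BoundsError(GaitDfaError):
    """Cycle indices fall outside the record."""


class EmptyResultError(GaitDfaError):
    """An operation that must produce output produced none."""


class SimSpecError(GaitDfaError):
    """Synthetic-data specification is infeasible."""


class EmbeddingError(GaitDfaError):
    """Circulant embedding produced materially negative spectral mass."""
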