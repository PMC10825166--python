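"""Exception types raised across the package."""


class CicsQuantError(Exception):
    """Base class for all package errors."""


class PlacementError(CicsQuantError):
    """Synthetic-field placement failed after bounded retries."""


class ChannelAssignmentError(CicsQuantError):
    """A file could not be assigned to exactly one channel role."""


class DimensionMismatchError(CicsQuantError):
    """Rasters that must be co-registered have different shapes."""


class MissingChannelError(CicsQuantError):
    """A required channel role is absent from the field of view."""


class UndefinedRateError(CicsQuantError):
    """A per-100-host-cell rate was requested with zero host cells."""


class ZeroControlError(CicsQuantError):
    """Fold-change normalisation against a zero-mean control."""


class ConfigError(CicsQuantError):
    """Invalid or unknown configuration keys/values."""


class InsufficientDataError(CicsQuantError):
    """Too few observations for the requested statistic."""
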