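"""Exception hierarchy for the pipeline.

Every error raised on bad scientific input derives from :class:`IsopulseError`
so batch drivers can catch one base class and keep going.
"""


class IsopulseError(Exception):
    """Base class for all domain errors."""


class InvalidIsotopeError(IsopulseError):
    """An isotopic value outside its physical domain (delta <= -1000 permil,
    atom fraction outside (0, 1))."""


class DegenerateMixingError(IsopulseError):
    """Two-pool mixing requested with identical end-members."""


class SingularFitError(IsopulseError):
    """A regression whose design matrix is singular (e.g. constant CO2 in a
    Keeling plot)."""


class InsufficientDataError(IsopulseError):
    """Fewer observations than the operation can work with."""


class AlignmentError(IsopulseError):
    """Paired series whose measurement windows do not overlap."""


class ConfigError(IsopulseError):
    """Invalid geometry, rate constant or other configuration value."""


class UndefinedSourceError(IsopulseError):
    """Source isotopic signature undefined because the chamber added no CO2
    over the buffer."""


class UndefinedIndexError(IsopulseError):
    """NDVI undefined (both reflectances zero)."""


class PairingError(IsopulseError):
    """A sample lacks its required baseline partner."""


class NormalizationError(IsopulseError):
    """Relative recovery requested with a nonpositive normalizer."""


class UnfittableError(IsopulseError):
    """Decay fit requested on data with no positive values."""


class UndefinedMRTError(IsopulseError):
    """Mean residence time requested from a fit with b <= 0 or no convergence."""


class InsufficientOverlapError(IsopulseError):
    """Lag scan overlap shorter than the required minimum."""


class DesignError(IsopulseError):
    """Invalid factor design for a permutation test (empty group, <2 levels)."""


class SchemaError(IsopulseError):
    """A table is missing required columns; the message names them."""
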