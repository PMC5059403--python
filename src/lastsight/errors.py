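"""Exception hierarchy shared across the package."""


class LastSightError(Exception):
    """Base class for all package-specific errors."""


class RecordParseError(LastSightError, ValueError):
    """A record file cell could not be parsed; names row and column."""


class RecordValidationError(LastSightError, ValueError):
    """A record table violates an invariant (duplicate lab code, missing field)."""


class CurveFormatError(LastSightError, ValueError):
    """A calibration-curve file is malformed or non-monotone."""


class CalibrationError(LastSightError, ValueError):
    """A radiocarbon determination cannot be calibrated on the given curve."""


class InsufficientDataError(LastSightError, ValueError):
    """Too few sightings for the requested estimator."""


class DegenerateRangeError(LastSightError, ValueError):
    """The observed sighting range (or youngest gap) is zero."""


class RateSaturationError(LastSightError, ValueError):
    """Sighting rate n/r >= 1; the McInerny extension is undefined."""


class NoValidPairError(LastSightError, ValueError):
    """Every pairwise sighting rate saturated; no weighted candidate exists."""


class ConditioningError(LastSightError, ValueError):
    """The optimal-linear-estimation weight system is numerically singular."""


class FitError(LastSightError, ValueError):
    """A maximum-likelihood distribution fit failed or did not converge."""


class SelectionError(LastSightError, ValueError):
    """No candidate family could be fitted during model selection."""


class CoverageError(LastSightError, ValueError):
    """The proxy series does not cover the requested correlation window."""


class UsageError(LastSightError, ValueError):
    """An unknown label or invalid option value was supplied."""
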