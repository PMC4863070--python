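"""Exception hierarchy for vo2overlap.

All package errors derive from :class:`VO2OverlapError` so callers can catch
one base class; the concrete subclasses map onto the distinct failure modes
of the analysis (bad user input, a calibration evaluated outside its domain,
an unknown device, insufficient data for a fit, a failed default recovery).
"""


class VO2OverlapError(Exception):
    """Base class for all vo2overlap errors."""


class InvalidInputError(VO2OverlapError, ValueError):
    """A user-supplied value violates a precondition (e.g. non-positive VO2)."""


class CalibrationDomainError(VO2OverlapError):
    """A calibration polynomial produced a non-positive sigma."""


class RangeError(VO2OverlapError):
    """A VO2 value lies outside the hard physiologic envelope."""


class UnknownDeviceError(VO2OverlapError, KeyError):
    """A device identifier is not present in the calibration registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class InsufficientDataError(VO2OverlapError):
    """Too few test-retest records to determine the requested polynomial."""


class RecoveryError(VO2OverlapError):
    """Default-calibration recovery failed (underdetermined or non-convergent)."""
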