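"""Exception hierarchy for warmpet.

All package-specific failures derive from :class:`WarmPetError` so callers
can catch one base class at pipeline level while tests can assert on the
specific failure mode.
"""


class WarmPetError(Exception):
    """Base class for all warmpet errors."""


class ScheduleError(WarmPetError):
    """Frame-timing table is malformed or inconsistent with the image."""


class FormatError(WarmPetError):
    """Input file is not in the expected format (e.g. non-4D image)."""


class RegionError(WarmPetError):
    """A requested region is missing or empty in the mask."""


class WindowError(WarmPetError):
    """A temporal window (peak search, SUVR) is not covered by the schedule."""


class DegenerateSignalError(WarmPetError):
    """A time-activity curve carries no usable signal (all nonpositive, zero spread...)."""


class NonWashoutError(WarmPetError):
    """The target curve does not decay over the washout phase, so the
    washout log-integral is non-negative and the binding estimate is undefined."""


class CalibrationError(WarmPetError):
    """Surrogate-flow calibration is impossible (nonpositive cohort mean or target)."""
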