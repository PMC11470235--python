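"""Exception hierarchy.

Every error raised by the package derives from :class:`ChronogramError`,
so callers can catch one type at pipeline boundaries while tests assert
on the specific subclasses.
"""


class ChronogramError(Exception):
    """Base class for all cohortgram errors."""


class MissingColumnError(ChronogramError):
    """A required column is absent from a table."""


class DuplicateKeyError(ChronogramError):
    """A {participant, date} key (or participant id) occurs more than once."""


class UnknownParticipantError(ChronogramError):
    """An experiment table references a participant absent from the metadata."""


class ColumnCollisionError(ChronogramError):
    """An incoming result column would overwrite an existing column."""


class DateSpanError(ChronogramError):
    """An observation is dated outside the chronogram's [start, end] span."""


class DateParseError(ChronogramError):
    """One or more cells could not be parsed as calendar days.

    ``failures`` holds (row_index, raw_value) pairs for reporting.
    """

    def __init__(self, message, failures=None):
        super().__init__(message)
        self.failures = list(failures or [])


class NonconstantMetadataError(ChronogramError):
    """A metadata column takes more than one value for a participant."""


class AnnotationOrderError(ChronogramError):
    """An annotation was requested before its prerequisite annotation ran."""


class AnnotationStateError(ChronogramError):
    """Existing annotation columns would be overwritten without consent."""


class UnknownMarkerValueError(ChronogramError):
    """A serological marker value is in neither the negative nor positive set."""


class FillConflictError(ChronogramError):
    """Multiple distinct values found within one episode under policy='error'."""


class DoseOrderError(ChronogramError):
    """Vaccine dose dates are not strictly increasing for a participant."""


class WindowError(ChronogramError):
    """Invalid window specification (e.g. offset_lo > offset_hi)."""


class SubcohortError(ChronogramError):
    """Invalid sub-cohorting request (unknown policy, missing reference...)."""


class UnsupportedVersionError(ChronogramError):
    """A saved chronogram declares a container format we cannot read."""


class IntegrityError(ChronogramError):
    """A saved chronogram fails checksum or internal-consistency checks."""


class DesignError(ChronogramError):
    """A synthetic cohort design violates its own constraints."""
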