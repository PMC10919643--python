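"""Exception hierarchy for dicscore."""

from __future__ import annotations


class DicscoreError(Exception):
    """Base class for all dicscore errors."""


class ValidationError(DicscoreError):
    """A record or configuration field violates its invariants."""


class ConfigurationError(DicscoreError):
    """A policy/config value is absent or inconsistent (e.g. zero reference PT)."""


class MissingDataError(DicscoreError):
    """A value required by the requested computation is missing.

    When raised by :func:`dicscore.scoring.score_all` the attributes
    ``partial`` (criterion -> CriterionScore for the criteria that could be
    scored) and ``failures`` (criterion -> message for those that could not)
    are populated so callers can recover the successful scores.
    """

    def __init__(self, message: str, *, partial=None, failures=None):
        super().__init__(message)
        self.partial = partial if partial is not None else {}
        self.failures = failures if failures is not None else {}


class EmptyCohortError(DicscoreError):
    """An evaluation was requested on an empty cohort."""


class MissingVariableError(DicscoreError):
    """A group-comparison variable is absent on every record."""


class CohortIOError(DicscoreError):
    """A cohort file could not be read or written."""
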