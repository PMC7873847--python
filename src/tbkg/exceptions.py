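"""Exception taxonomy for the tbkg pipeline.

Every stage raises one of these so the command-line driver can map
failures onto distinct exit codes (validation vs. missing/unreadable
input) without string matching.
"""


class TBKGError(Exception):
    """Base class for all tbkg errors."""


class FormatError(TBKGError):
    """An input file could not be parsed in its declared format."""


class ValidationError(TBKGError):
    """Input parsed but violates a structural contract (duplicate ids,
    type-invalid edge, unknown semantic category in strict mode, ...)."""


class ConflictError(ValidationError):
    """The same node pair was inserted with two different weights."""


class DegenerateTargetError(ValidationError):
    """A naive-Bayes target entity has zero positive documents."""


class UndefinedImportanceError(TBKGError):
    """Importance is undefined because an unsmoothed conditional is zero."""


class UndefinedStatisticError(TBKGError):
    """An agreement statistic has a zero denominator.

    Carries the statistic's name so callers can report which of
    kappa/sensitivity/specificity failed.
    """

    def __init__(self, statistic: str, message: str | None = None):
        self.statistic = statistic
        super().__init__(message or f"{statistic} is undefined for this table")


class ConfigurationError(TBKGError):
    """A run configuration is internally inconsistent (bad fold count,
    labeled fractions that would overlap, empty gold list, ...)."""


class UnknownEntityError(TBKGError, KeyError):
    """A referenced entity (doc id, concept id, graph node) does not exist."""

    def __str__(self) -> str:  # KeyError quotes its argument; keep the message readable
        return Exception.__str__(self)
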