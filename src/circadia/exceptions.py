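"""Exception hierarchy for circadia.

All errors raised by the library derive from :class:`CircadiaError` so callers
can catch the package's failures with a single except clause.
"""


class CircadiaError(Exception):
    """Base class for all circadia errors."""


class ConfigurationError(CircadiaError):
    """A configuration value is invalid; the message names the field."""


class FormatError(CircadiaError):
    """An input file is missing a required column or is otherwise unreadable."""


class DegenerateProfileError(CircadiaError):
    """An intensity or activity profile has zero total mass."""


class DegenerateCohortError(CircadiaError):
    """A cohort is empty or contains no events to normalize."""


class LocalizationError(CircadiaError):
    """A timezone string cannot be resolved to an offset rule."""


class UndefinedRatioError(CircadiaError):
    """A ratio is undefined because its denominator is zero."""


class UndefinedCorrelationError(CircadiaError):
    """Pearson correlation is undefined for a constant series."""


class MatchingError(CircadiaError):
    """Creation-month matched sampling cannot satisfy the reference quotas."""


class SparseHourError(CircadiaError):
    """An hour-of-day stratum has no tweets in one of the cohorts."""
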