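"""Exception hierarchy for ardsrec.

Every stage raises a subclass of :class:`ArdsrecError` so that pipeline
drivers can distinguish analysis failures from programming errors.
"""


class ArdsrecError(Exception):
    """Base class for all ardsrec-specific errors."""


class InvalidInputError(ArdsrecError, ValueError):
    """An argument violates a precondition (non-positive height, empty list...)."""


class ConfigError(ArdsrecError, ValueError):
    """A cohort or analysis configuration is infeasible or inconsistent."""


class NotInCohortError(InvalidInputError):
    """A value falls outside the cohort inclusion rules (e.g. P/F > 300)."""


class DegenerateInputError(InvalidInputError):
    """Input has no usable variation (constant vector, all-missing factor)."""


class CollinearityError(ArdsrecError):
    """Rank-deficient regression design; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns: {', '.join(self.columns)}")


class InvalidFactorError(InvalidInputError):
    """A regression factor is not applicable to the requested cohort."""


class EmptyResultError(ArdsrecError):
    """A filter removed every record."""


class InsufficientDataError(InvalidInputError):
    """Too few points to fit (KDE needs >= 5, references must be non-empty)."""


class UndefinedOddsError(ArdsrecError):
    """Both class densities vanish at the query point; the odds are 0/0."""


class SubgroupViolationError(InvalidInputError):
    """A record was passed to a stage reserved for a different subgroup."""


class BinningMismatchError(InvalidInputError):
    """Histograms entering one mixture fit were built on different bins."""


class UnidentifiableError(ArdsrecError):
    """The two reference histograms coincide; the mixture fraction has no
    unique value."""


class SmallStratumError(InvalidInputError):
    """A severity stratum is too small to bootstrap (fewer than 5 records)."""


class SchemaError(ArdsrecError):
    """A cohort CSV is missing required columns; carries their names."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")
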