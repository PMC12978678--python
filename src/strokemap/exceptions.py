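"""Exception hierarchy for the strokemap pipeline.

All errors derive from :class:`StrokemapError` so callers can catch the
package's failures with a single except clause while still distinguishing
data problems (bad inputs) from configuration problems (bad settings).
"""


class StrokemapError(Exception):
    """Base class for all strokemap errors."""


class CohortConsistencyError(StrokemapError):
    """Lesion masks in a cohort disagree in shape or affine."""


class DimensionalityError(StrokemapError):
    """An image does not have the expected number of dimensions."""


class AlignmentError(StrokemapError):
    """Parcel labels or subject orders do not line up across inputs."""


class DataError(StrokemapError):
    """Invalid values in the data (NaN, negatives where forbidden, ...)."""


class CollinearityError(StrokemapError):
    """The covariate design matrix is rank deficient."""

    def __init__(self, message, dependent_columns=()):
        super().__init__(message)
        self.dependent_columns = tuple(dependent_columns)


class EmptyDesignError(StrokemapError):
    """No features survive the coverage / disconnection filters."""


class InsufficientCohortError(StrokemapError):
    """Too few subjects remain for a meaningful multivariate fit."""


class ConfigurationError(StrokemapError):
    """A configuration value is outside its allowed range."""
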