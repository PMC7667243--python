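"""Exception hierarchy.

Every error the package raises derives from :class:`PidotError`, so callers
can catch one type at a pipeline boundary.
"""


class PidotError(Exception):
    """Base class for all pidotkit errors."""


class MappingError(PidotError):
    """A file channel cannot be mapped onto the panel (names the channel)."""


class FormatError(PidotError):
    """Malformed or truncated FCS/CSV input."""


class ParameterError(PidotError):
    """An operation parameter is out of its documented domain."""


class InsufficientEventsError(PidotError):
    """Too few events for a statistic to be meaningful."""


class RegistryError(PidotError):
    """Population template registry violates the hierarchy contract."""


class InsufficientDataError(PidotError):
    """An age bin (or similar stratum) has too few samples."""


class ConfigurationError(PidotError):
    """Gate tree / threshold configuration is internally inconsistent."""


class MetadataError(PidotError):
    """Required sample metadata (age, WBC) missing or invalid."""


class BuildError(PidotError):
    """Reference database cannot be built from the given cohort."""


class NumericError(PidotError):
    """Numerical failure (e.g. singular covariance despite shrinkage)."""


class RangeCoverageError(PidotError):
    """Sample age falls in an age bin with no derived reference range."""


class InputError(PidotError):
    """Malformed statistical input (mismatched sets, zero margins, ...)."""


class DomainError(PidotError):
    """Value outside the mathematical domain of a formula."""


class LeakageError(PidotError):
    """Evaluation samples overlap the database training cohort."""
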