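"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`DentageError`, so callers can catch one type at a pipeline
boundary and still distinguish fine-grained failures when needed.
"""


class DentageError(Exception):
    """Base class for all errors raised by dentage."""


class FormatError(DentageError):
    """A file does not conform to one of the package's tabular formats."""


class VocabularyError(FormatError):
    """A landmark label outside the closed 36-label vocabulary."""


class DuplicateLandmarkError(FormatError):
    """The same (case_id, label) pair appears more than once."""


class ParseError(FormatError):
    """A cell could not be parsed as the required type."""


class SchemaVersionError(FormatError):
    """A persisted model file carries an unknown schema tag."""


class AgeRangeError(DentageError):
    """An age in months outside the validity window of the method."""


class MissingLandmarkError(DentageError):
    """A segment endpoint is absent from a landmark set."""


class MissingFeatureError(DentageError):
    """A required input variable is absent from a feature vector."""


class DegenerateColumnError(DentageError):
    """A column has zero range, so min-max scaling is undefined."""


class CapacityError(DentageError):
    """More hidden units requested than training cases available."""


class NumericalError(DentageError):
    """A linear solve failed; typically fixed by setting ridge > 0."""


class UndefinedQualityError(DentageError):
    """Correlation is undefined (fewer than 2 cases or zero variance)."""


class SizeError(DentageError, ValueError):
    """A case collection is too small for the requested operation."""


class ConfigurationError(DentageError, ValueError):
    """An invalid search / pipeline configuration."""


class PruningError(DentageError):
    """Pruning would remove every input variable."""


class ParameterError(DentageError, ValueError):
    """Invalid generator or template parameters."""
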