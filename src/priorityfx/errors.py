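"""Exception hierarchy shared across the pipeline."""


class PriorityFxError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PriorityFxError):
    """Input data violate a precondition (empty, non-finite, out of range)."""


class ParseError(PriorityFxError):
    """A raw table cell could not be interpreted; message names the row."""


class SchemaError(PriorityFxError):
    """A required column is missing or has the wrong type."""


class ConfigurationError(PriorityFxError):
    """A run configuration value is out of its admissible range."""


class UndefinedIndexError(PriorityFxError):
    """Both members of a performance pair are zero: the index is undefined."""


class UndefinedReferenceError(PriorityFxError):
    """Percent change requested against a non-positive reference mean."""


class InsufficientDataError(PriorityFxError):
    """Fewer observations than the estimator needs."""


class AliasingError(PriorityFxError):
    """Rank-deficient design matrix; message names an aliased column."""


class DomainError(PriorityFxError):
    """A value is outside the mathematical domain of the operation."""
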