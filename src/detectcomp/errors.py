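"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`DetectCompError`, so callers (and
the command-line wrapper) can distinguish bad input (validation/schema) from
analyses that are impossible on the data provided (insufficient data,
degenerate designs).
"""


class DetectCompError(Exception):
    """Base class for all errors raised by detectcomp."""


class SchemaError(DetectCompError):
    """The input file is missing mandatory columns or is otherwise unreadable."""


class ValidationError(DetectCompError):
    """One or more rows violate the study-table invariants."""


class DomainError(DetectCompError):
    """A numeric argument is outside its mathematical domain (e.g. log of 0)."""


class InsufficientDataError(DetectCompError):
    """Too few observations for the requested fit or resampling scheme."""


class DegenerateDesignError(DetectCompError):
    """The design matrix carries no information (all-zero x, single category)."""


class DegenerateResidualsError(DetectCompError):
    """Residual scale is exactly zero, so studentization is undefined."""


class InconsistentTaxonomyError(DetectCompError):
    """The same species is assigned to different higher taxa across rows."""


class SingularCovarianceError(DetectCompError):
    """The phylogenetic covariance matrix is not positive definite."""
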