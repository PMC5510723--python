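"""Exception hierarchy for mrsummary.

All library errors derive from :class:`MRError` so callers can catch a single
base class; finer-grained subclasses separate structural problems in the input
data from numerical failures in the estimators.
"""


class MRError(Exception):
    """Base class for all mrsummary errors."""


class DataStructureError(MRError, ValueError):
    """Summarized data vectors are inconsistent (length mismatch, bad field)."""


class StandardErrorError(MRError, ValueError):
    """A standard error is non-positive or non-finite."""


class CorrelationMatrixError(MRError, ValueError):
    """Between-variant correlation matrix violates its invariants."""


class HarmonizationError(MRError, ValueError):
    """Allele harmonization cannot proceed (e.g. no shared variants)."""


class InsufficientVariantsError(MRError, ValueError):
    """An estimator was given fewer variants than it requires."""


class DegenerateDesignError(MRError, ValueError):
    """Regression design is rank-deficient (constant x, all-zero weights...)."""


class ConvergenceError(MRError, RuntimeError):
    """An iterative fit failed to converge."""


class SchemaError(MRError, ValueError):
    """A delimited-text file is missing required columns or is malformed."""


class SelectionError(MRError, ValueError):
    """A record query (trait / PubMed ID / ancestry) matched nothing."""


class AmbiguityError(MRError, ValueError):
    """Duplicate conflicting records for the same variant and query."""
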