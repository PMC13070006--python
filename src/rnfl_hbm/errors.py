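"""Exception hierarchy shared across the package."""


class CohortError(ValueError):
    """Base class for cohort validation and pipeline errors."""


class SchemaError(CohortError):
    """A required column is missing or has the wrong type."""


class UniquenessError(CohortError):
    """Duplicate (subject, visit, sector) records."""


class ConsistencyError(CohortError):
    """Cross-field or cross-file invariant violated."""


class EmptyCohortError(CohortError):
    """A filtering step removed every subject."""


class DegenerateCovariateError(CohortError):
    """A covariate has zero variance and cannot be standardized."""


class DimensionError(CohortError):
    """An array input has the wrong length or shape."""


class ConfigError(CohortError):
    """Infeasible or inconsistent configuration."""


class NamingError(CohortError):
    """A referenced covariate or parameter name does not exist."""


class ConvergenceError(RuntimeError):
    """MCMC diagnostics failed; carries the diagnostic table."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class InsufficientChainsError(ValueError):
    """Convergence diagnostics need at least two chains."""


class ProvenanceError(ValueError):
    """Summaries combined across objects from different fits."""
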