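"""Exception hierarchy for the greencomp pipeline.

Every stage raises a subclass of :class:`GreencompError` so callers
(and the CLI) can abort with a stage-named message.
"""


class GreencompError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GreencompError, ValueError):
    """A configuration value violates its contract (probabilities not
    summing to one, negative noise SD, missingness rate outside [0, 1], ...)."""


class SchemaError(GreencompError, ValueError):
    """A cohort table does not match the fixed column schema, or a field
    name is unknown."""


class ClassificationError(GreencompError, ValueError):
    """Metabolic syndrome classification was attempted on a record with a
    missing component; callers must complete-case filter first."""


class DegenerateDistributionError(GreencompError, ValueError):
    """The empirical exposure distribution cannot support an intervention
    grid (fewer than two distinct values)."""


class SingularDesignError(GreencompError, ValueError):
    """The regression design matrix is rank deficient.  The message names
    the offending column(s), e.g. an empty category level."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(
            message
            or "singular design matrix; offending column(s): "
            + ", ".join(self.columns)
        )


class ConvergenceError(GreencompError, RuntimeError):
    """An iteratively fitted model failed to converge and the caller asked
    for a hard failure."""


class BootstrapError(GreencompError, RuntimeError):
    """Too many bootstrap refits failed (more than the tolerated fraction)."""


class EmptyStratumError(GreencompError, ValueError):
    """A partial intervention targeted a modifier stratum with no members."""


class PipelineStageError(GreencompError, RuntimeError):
    """A pipeline stage aborted; the message names the stage and partial
    outputs have been removed."""


class HeterogeneityError(GreencompError, ValueError):
    """A Cochran Q test was requested on degenerate input (single stratum,
    or a stratum with zero standard error)."""
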