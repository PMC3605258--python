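"""Exception hierarchy shared across the package."""


class SurvcutError(Exception):
    """Base class for all package errors."""


class DataError(SurvcutError, ValueError):
    """Malformed or out-of-contract input data."""


class SpecError(SurvcutError, ValueError):
    """Invalid simulation or analysis specification."""


class CohortTooSmallError(DataError):
    """Cohort below the minimum size an operation requires."""


class MappingError(DataError):
    """Probe-set or gene identifiers missing from an input matrix."""


class DegenerateProbesetError(DataError):
    """A probe-set row with zero variance cannot be standardized."""


class SingularMatrixError(DataError):
    """Collinear or constant covariates make the information matrix singular."""


class UndefinedTestError(DataError):
    """A test statistic is undefined for the given data (e.g. no events)."""


class ConstraintError(SurvcutError, ValueError):
    """No candidate satisfies the stated search constraints."""


class PipelineError(SurvcutError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
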