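"""Exception hierarchy shared across the pipeline.

Distinct classes map to distinct CLI exit codes, so schema problems,
bad configuration and fit failures are distinguishable to callers.
"""


class QuiescreenError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(QuiescreenError):
    """An input table is missing columns or has unparseable structure."""

    exit_code = 3


class ValidationError(QuiescreenError):
    """Parsed data violate an invariant (duplicate wells, bad roles, ...)."""

    exit_code = 3


class ConfigError(QuiescreenError):
    """Run or simulation configuration is inconsistent."""

    exit_code = 2


class InsufficientDesignError(QuiescreenError):
    """Too few distinct doses/timepoints to identify the model."""

    exit_code = 4


class NormalizationError(QuiescreenError):
    """Plate control statistics unusable for normalization (mu_neg <= 0)."""

    exit_code = 3


class AmbiguityError(ValidationError):
    """A compound appears more than once where a single well is expected."""


class ConvergenceError(QuiescreenError):
    """An optimiser failed to converge."""

    exit_code = 4
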