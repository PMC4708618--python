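"""Exception hierarchy for spillover-aware cost-effectiveness analysis."""


class SpilloverCEAError(Exception):
    """Base class for all package-specific errors."""


class UndefinedMultiplierError(SpilloverCEAError, ZeroDivisionError):
    """Multiplier is undefined because the patient health change is zero.

    The ratio form of the decision rule divides by patient health; callers
    hitting this should fall back to :func:`direct_spillover_decision`,
    which compares the two health streams without forming a ratio.
    """


class ZeroDisplacedHealthError(SpilloverCEAError):
    """Total displaced health is non-positive, so no threshold is defined."""


class UnboundedDemandError(SpilloverCEAError):
    """A flat marginal-benefit schedule sits above the loss schedule everywhere."""


class SingularDesignError(SpilloverCEAError):
    """Regression design matrix is rank deficient.

    Carries the names of the offending (collinear or constant) columns in
    ``columns``.
    """

    def __init__(self, message: str, columns: tuple = ()):  # noqa: D107
        super().__init__(message)
        self.columns = tuple(columns)


class SchemaError(SpilloverCEAError):
    """Input file violates the expected schema; message names row and column."""


class ConfigurationError(SpilloverCEAError):
    """Invalid or internally inconsistent configuration."""
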