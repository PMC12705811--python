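"""Exception hierarchy shared across the package."""


class BiofaboptError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(BiofaboptError):
    """The requested experimental design is structurally invalid."""


class InvalidFactorError(BiofaboptError):
    """A factor definition violates its constraints (e.g. non-positive step)."""


class DimensionError(BiofaboptError):
    """Vector lengths do not match the factor list."""


class IncompleteDataError(BiofaboptError):
    """An operation requires responses that are missing."""


class RankDeficiencyError(BiofaboptError):
    """The model matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"model matrix is rank deficient; collinear columns: {self.columns}")


class DegenerateDataError(BiofaboptError):
    """The response carries no usable variation."""


class DomainError(BiofaboptError):
    """An input lies outside the mathematical domain of the operation."""


class ConfigurationError(BiofaboptError):
    """Inconsistent user-supplied configuration."""


class InfeasibleError(BiofaboptError):
    """No feasible point exists for the optimization problem."""


class TrainingFailureError(BiofaboptError):
    """Every training restart diverged."""


class NotEstimableError(BiofaboptError):
    """The requested quantity cannot be estimated from the data given."""


class SchemaError(BiofaboptError):
    """A file does not conform to the documented CSV dialect."""


class IntegrityError(BiofaboptError):
    """A bundled fixture failed its checksum."""
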