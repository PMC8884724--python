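"""Shared exception types."""


class AisleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AisleError):
    """Input table or config does not match the expected schema."""


class DegenerateDataError(AisleError):
    """A statistical routine received data it cannot fit (single group,
    constant input, empty set)."""


class SeparationError(AisleError):
    """Complete or quasi-complete separation in a logistic model."""


class CollinearityError(AisleError):
    """Near-perfect collinearity between model regressors."""
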