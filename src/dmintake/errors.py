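"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: usage errors -> 2, data/schema errors -> 3,
numerical failures -> 4.
"""


class DMIntakeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DMIntakeError, ValueError):
    """A scalar input violates its documented domain (e.g. BW <= 0)."""


class MissingPredictorError(DMIntakeError, ValueError):
    """A prediction equation is missing a required predictor.

    The offending field name is stored in ``field``.
    """

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"missing required predictor: {field!r}")


class ConfigurationError(DMIntakeError, ValueError):
    """An option or configuration value is not recognised or inconsistent."""


class SchemaError(DMIntakeError, ValueError):
    """A tabular input does not match the documented column schema."""


class DataError(DMIntakeError, ValueError):
    """Data are structurally valid but unusable (e.g. empty after filtering)."""


class DesignError(DMIntakeError, ValueError):
    """A regression design matrix is rank deficient or degenerate."""


class FitError(DMIntakeError, RuntimeError):
    """A numerical fitting routine failed to produce usable estimates."""


class DegenerateInputError(DMIntakeError, ValueError):
    """A sample is degenerate for the requested operation (e.g. constant)."""
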