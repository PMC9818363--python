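"""Exception hierarchy for powderlife."""


class PowderlifeError(Exception):
    """Base class for all powderlife errors."""


class DomainError(PowderlifeError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class RangeError(PowderlifeError, ValueError):
    """A requested value lies outside the attainable range of a model."""


class InsufficientDataError(PowderlifeError, ValueError):
    """Too few observations to carry out a fit or comparison."""


class FitFailureError(PowderlifeError, RuntimeError):
    """Nonlinear fitting failed to converge across all restarts."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(PowderlifeError, ValueError):
    """A tabular input does not conform to the storage-table schema."""


class ConfigError(PowderlifeError, ValueError):
    """A configuration file or object is invalid."""
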