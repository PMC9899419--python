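"""Exception hierarchy for the grainfill package."""


class GrainfillError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GrainfillError):
    """An input table does not have the expected columns or layout."""


class ValidationError(GrainfillError):
    """Input values violate a documented invariant."""


class UnitError(ValidationError):
    """Inconsistent or unknown content units."""


class NotConvergedError(GrainfillError):
    """An operation requiring a converged fit received a failed one."""
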