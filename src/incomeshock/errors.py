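"""Exception types shared across the package."""


class IncomeShockError(Exception):
    """Base class for package errors."""


class SchemaError(IncomeShockError):
    """A required column or field is missing or misnamed."""


class ValidationError(IncomeShockError, ValueError):
    """A value violates a model invariant (negative money, bad probability...)."""


class LookupError_(IncomeShockError, KeyError):
    """A table lookup (age/gender) fell outside the table's range."""
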