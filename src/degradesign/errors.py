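"""Exception hierarchy shared by all degradesign modules."""


class DegradesignError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(DegradesignError):
    """A required column (or column mapping) is missing or malformed."""


class ValidationError(DegradesignError):
    """Input data violates an invariant (duplicate ids, bad numerics, ...)."""


class LevelMismatchError(ValidationError):
    """A DOE cell holds a value not among its factor's declared levels."""


class DomainError(DegradesignError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ShapeError(DegradesignError):
    """Array/list lengths are inconsistent with one another."""


class UnitError(DegradesignError):
    """Energetic components carry incompatible unit tags."""
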