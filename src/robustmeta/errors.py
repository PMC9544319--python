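"""Exception hierarchy."""


class RobustMetaError(Exception):
    """Base class for all robustmeta errors."""


class SchemaError(RobustMetaError):
    """An input file does not have the expected columns or format."""


class DataValidationError(RobustMetaError):
    """Input values violate a domain invariant (e.g. responders > arm size)."""


class ConstraintError(RobustMetaError):
    """A quality-constraint system is infeasible, cyclic, or misused."""
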