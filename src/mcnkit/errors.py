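"""Exception hierarchy shared across the pipeline."""


class McnkitError(ValueError):
    """Base class for all mcnkit errors."""


class SchemaError(McnkitError):
    """A table does not conform to the documented column schema."""


class AlignmentError(McnkitError):
    """Subject identifiers cannot be aligned across input tables."""


class ValidationError(McnkitError):
    """A value violates a domain invariant (e.g. non-positive volume)."""


class ConfigError(McnkitError):
    """A simulation or analysis configuration is invalid."""
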