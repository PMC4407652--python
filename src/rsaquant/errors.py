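"""Exception hierarchy shared across the package."""


class RsaQuantError(Exception):
    """Base class for all rsaquant errors."""


class ParseError(RsaQuantError):
    """Input document could not be parsed (malformed XML/CSV)."""


class SchemaError(RsaQuantError):
    """Input is parseable but its columns/fields do not match the contract."""


class ValidationError(RsaQuantError):
    """Parsed content violates a structural invariant (bad root, bad ref)."""

    def __init__(self, message: str, *, root_id: str | None = None,
                 plant_id: str | None = None):
        super().__init__(message)
        self.root_id = root_id
        self.plant_id = plant_id


class DegenerateInputError(RsaQuantError):
    """Geometric input has no usable extent (zero total length, empty set)."""
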