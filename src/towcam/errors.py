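"""Exception types shared across the package."""


class TowcamError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TowcamError):
    """An input table is missing required columns or has a malformed layout."""


class ValidationError(TowcamError):
    """An input value violates a domain invariant (negative count, duplicate frame...)."""


class CalibrationError(TowcamError):
    """Requested simulation targets lie outside the feasible region of the model."""
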