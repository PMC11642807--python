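"""Exception types shared across the package."""


class TauspreadError(Exception):
    """Base class for package errors."""


class SchemaError(TauspreadError):
    """An input table is missing required columns or has the wrong shape."""


class ValidationError(TauspreadError):
    """Input content violates a documented invariant."""


class UnfittableError(TauspreadError):
    """A model fit cannot be computed from the data provided."""
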