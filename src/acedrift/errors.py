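"""Exception hierarchy shared across the package.

CLI exit-code convention: usage errors exit 2 (click), data/schema errors 3,
numeric failures 4.
"""


class AceDriftError(Exception):
    """Base class for package errors."""


class DataSchemaError(AceDriftError):
    """An input file does not match the expected schema (missing column,
    unparseable cell)."""


class RecordValidationError(AceDriftError):
    """A record set violates a structural invariant (bounds, chain linkage,
    seed size)."""


class NumericFailure(AceDriftError):
    """A numeric procedure could not produce a result (degenerate statistic,
    bracketing failure)."""
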