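"""Exception hierarchy for protocol, encoding and configuration failures."""


class MPCError(Exception):
    """Base class for all package-specific errors."""


class EncodingRangeError(MPCError, ValueError):
    """A real value does not fit the fixed-point representable range."""


class ConfigurationError(MPCError, ValueError):
    """Invalid parameter combination (party counts, sigmoid mode, ...)."""


class DimensionError(MPCError, ValueError):
    """Shape mismatch between shared operands."""


class ShareFormatError(MPCError, ValueError):
    """Malformed share tuple: missing, duplicate or inconsistent party indices."""


class BackendMismatchError(MPCError, ValueError):
    """Operands live on different numeric backends."""


class ProtocolError(MPCError, RuntimeError):
    """Violation of a protocol precondition (wrong party count, missing role)."""


class TripleReuseError(ProtocolError):
    """A Beaver triple was presented for a second multiplication."""


class NumericFailureError(MPCError, RuntimeError):
    """Non-finite intermediate values or divergence during training/inversion."""


class SchemaMismatchError(MPCError, ValueError):
    """Input parties disagree on the CSV schema."""
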