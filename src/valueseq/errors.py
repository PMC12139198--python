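"""Exception hierarchy shared across the package."""


class ValueSeqError(Exception):
    """Base class for all valueseq errors."""


class InvalidParameterError(ValueSeqError, ValueError):
    """A numeric argument violates its precondition (sign, finiteness, range)."""


class InsufficientDataError(ValueSeqError):
    """Too few observations to evaluate the requested quantity."""


class ConfigurationError(ValueSeqError):
    """A design/grid configuration is internally inconsistent."""


class SchemaError(ValueSeqError):
    """An input file does not match the expected schema."""


class IncompatibleFileError(ValueSeqError):
    """A serialised artifact was written by an incompatible format version."""
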