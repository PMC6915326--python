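"""Exception hierarchy shared by all pipeline stages."""


class CuicError(Exception):
    """Base class for all errors raised by this package."""


class InputError(CuicError, ValueError):
    """Malformed or out-of-contract input data (bad characters, empty sets...)."""


class ConfigError(CuicError, ValueError):
    """Invalid parameter or configuration value."""


class FormatError(CuicError, ValueError):
    """Structurally invalid file or record (e.g. unbalanced dot-bracket)."""


class UndefinedResultError(CuicError, ValueError):
    """The requested quantity is mathematically undefined on this input."""
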