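"""Exception taxonomy shared by all stages.

UsageError / ConfigError map to CLI exit code 2, DataError and ParseError to 1.
"""


class Cas9KitError(Exception):
    """Base class for all package errors."""


class UsageError(Cas9KitError, ValueError):
    """Caller passed arguments that violate an operation's contract."""


class ConfigError(Cas9KitError, ValueError):
    """Invalid run configuration (unknown key, inconsistent preset, ...)."""


class ParseError(Cas9KitError, ValueError):
    """Malformed input file; message names the file and offending record/line."""


class DataError(Cas9KitError, ValueError):
    """Input data that parses but cannot be analyzed (e.g. no cleavage evidence)."""
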