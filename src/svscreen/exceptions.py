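"""Exception hierarchy for svscreen.

Readers and statistical routines raise these instead of silently coercing
bad input; every error message carries enough context (file, row, column,
sample) to locate the offending record.
"""


class SvScreenError(Exception):
    """Base class for all svscreen errors."""


class ConfigError(SvScreenError):
    """Invalid configuration (bad fractions, missing control condition...)."""


class ParseError(SvScreenError):
    """Malformed value in an input file."""


class SchemaError(SvScreenError):
    """Structurally invalid input (missing metadata, duplicate names...)."""


class DataError(SvScreenError):
    """Input parsed but is unusable (zero-total sample, empty intersection)."""


class LibraryError(SvScreenError):
    """Invalid sgRNA library (duplicate guide ids or spacer sequences)."""


class StatError(SvScreenError):
    """Invalid arguments to a statistical routine."""
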