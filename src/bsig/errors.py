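"""Typed exception hierarchy.

Every malformed input raises one of these; no operation returns a silent
partial object.
"""


class BsigError(Exception):
    """Base class for all errors raised by bsig."""


class FormatError(BsigError):
    """A file violates its declared format (duplicate ids, short GMT line, ...)."""


class ParseError(FormatError):
    """A single cell could not be parsed; the message names the row and column."""


class ConsistencyError(BsigError):
    """Two inputs that must agree do not (e.g. metadata missing a matrix sample)."""


class ConfigError(BsigError):
    """A configuration value is outside its documented domain."""


class AnalysisError(BsigError):
    """A computation was requested on data that cannot support it."""
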