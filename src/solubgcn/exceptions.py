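"""Exception hierarchy.

All errors raised by this package derive from :class:`SolubGCNError` so callers
can catch them with a single ``except`` clause; the concrete subclasses also
inherit from the matching builtin (``ValueError`` / ``KeyError``) so generic
handling keeps working.
"""


class SolubGCNError(Exception):
    """Base class for all package errors."""


class ShapeError(SolubGCNError, ValueError):
    """A matrix or vector has the wrong shape or dimension."""


class ParseError(SolubGCNError, ValueError):
    """A text input could not be parsed; message carries file/row/column."""


class ConfigError(SolubGCNError, ValueError):
    """An invalid configuration value (unknown scheme, bad threshold, ...)."""


class AlignmentError(SolubGCNError, ValueError):
    """Per-residue inputs for one protein disagree on sequence length."""


class DataError(SolubGCNError, KeyError):
    """A required record, block or label is missing from the dataset."""
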