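"""Exception hierarchy.

Validation problems (bad input files, violated preconditions) raise
:class:`ValidationError`; numerical problems inside a single OTU pair raise
:class:`PairSkippedError`, which the all-pairs drivers catch and record as a
gap rather than aborting the whole matrix.
"""


class MccnError(Exception):
    """Base class for all package errors."""


class ValidationError(MccnError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """A file could not be parsed; the message names the offending cell."""


class EmptyFilterError(MccnError):
    """Every OTU was removed by the prevalence/abundance filters."""


class PairSkippedError(MccnError):
    """A single OTU pair could not be tested (collinear or singular fit)."""


class InsufficientDataError(MccnError):
    """Too few usable observations for the requested model."""
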