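"""Exception hierarchy shared by all pipeline stages."""


class P2NError(Exception):
    """Base class for all package errors."""


class FormatError(P2NError):
    """A file does not conform to its declared format (GMT/SIF/TSV/GAF)."""


class ValidationError(P2NError):
    """An input violates a documented precondition or invariant."""


class FitUndefinedError(P2NError):
    """A degree distribution too degenerate for a power-law regression."""
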