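"""Exception hierarchy shared by all meanet modules."""


class MeanetError(Exception):
    """Base class for all meanet errors."""


class FormatError(MeanetError, ValueError):
    """A file could not be parsed (malformed row, bad header, ...)."""


class ValidationError(MeanetError, ValueError):
    """An input violates a documented precondition or invariant."""


class AnalysisError(MeanetError, RuntimeError):
    """A computation is undefined for the given data (e.g. no active
    channels, empty graph, zero baseline rate)."""
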