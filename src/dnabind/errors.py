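"""Exception hierarchy shared by all dnabind modules."""


class DnabindError(Exception):
    """Base class for all errors raised by dnabind."""


class ValidationError(DnabindError, ValueError):
    """Input violates a documented precondition (bad alphabet, negative
    concentration, inverted restraint bounds, ...)."""


class ParseError(DnabindError, ValueError):
    """A file or table could not be parsed; the message names the offending
    row or cell."""


class InsufficientDataError(DnabindError):
    """Too few data points for the requested operation."""


class NoBindingSignalError(DnabindError):
    """The data carry no detectable binding signal (non-negative Scatchard
    slope, single spectral species, zero-DNA titration)."""


class UnsupportedModelError(DnabindError):
    """The estimated number of spectral species is outside the two-species
    pathway this package implements."""


class DegenerateAnchorError(DnabindError):
    """The free- and bound-state score anchors coincide, so molar fractions
    are undefined."""
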