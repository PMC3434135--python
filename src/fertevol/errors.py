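"""Exception types shared across the package."""


class FertevolError(Exception):
    """Base class for all package errors."""


class NewickParseError(FertevolError):
    """Raised when a Newick string cannot be parsed; message names the position."""


class ValidationError(FertevolError):
    """Raised on invalid inputs (duplicate labels, missing trait values, ...)."""


class CladeLookupError(FertevolError, KeyError):
    """Raised when a named clade cannot be resolved on a tree."""


class StructureError(FertevolError):
    """Raised when a tree's shape is unsuitable (e.g. polytomy where a
    bifurcating tree is required)."""


class UndefinedRateError(FertevolError):
    """Raised when an event rate is requested for a clade in which the event
    cannot occur (zero applicable genes)."""


class DegenerateNullError(FertevolError):
    """Raised when the binomial null probability is undefined (zero total
    exposure)."""


class InsufficientDataError(FertevolError):
    """Raised when too few observations exist for an estimate (e.g. a
    confidence interval with fewer than three tips)."""
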