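"""Exception hierarchy for manifuse.

All library errors derive from :class:`ManifuseError` so callers can catch
one base class; the concrete subclasses additionally derive from the
matching builtin (``ValueError`` / ``ArithmeticError``) so code written
against standard idioms keeps working.
"""


class ManifuseError(Exception):
    """Base class for all manifuse errors."""


class InvalidImageError(ManifuseError, ValueError):
    """An input array is not a valid grayscale image (shape, range, NaN...)."""


class ShapeMismatchError(InvalidImageError):
    """Two arrays that must be co-registered have different shapes."""


class InvalidParameterError(ManifuseError, ValueError):
    """A filter/metric/generator parameter is out of its valid domain."""


class DegenerateWeightError(ManifuseError, ArithmeticError):
    """A weighted average collapsed to a zero denominator."""
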