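"""Exception hierarchy.

All package errors derive from :class:`CophyloError` so callers (and the CLI)
can distinguish input/contract problems from degenerate statistics.
"""


class CophyloError(Exception):
    """Base class for all package errors."""


class ValidationError(CophyloError, ValueError):
    """An input violates a documented precondition or invariant."""


class NewickParseError(ValidationError):
    """Malformed Newick input; the message names the offending position."""


class DuplicateLabelError(ValidationError):
    """Tip labels within one tree must be unique."""


class SizeGuardError(ValidationError):
    """Instance exceeds the explicit size guard of an exhaustive routine."""


class DegenerateStatisticError(CophyloError, ArithmeticError):
    """A statistic is undefined on this input (e.g. zero-median null)."""
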