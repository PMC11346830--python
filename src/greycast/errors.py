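"""Exception hierarchy for greycast.

All library-raised errors derive from :class:`GreycastError` so callers can
catch everything with one clause; the two subclasses map onto the CLI's
exit codes (validation -> 2, degenerate model -> 3).
"""


class GreycastError(Exception):
    """Base class for all greycast errors."""


class ValidationError(GreycastError, ValueError):
    """Input data violates a contract (shape, sign, ordering, file format)."""


class DegenerateModelError(GreycastError, ArithmeticError):
    """The GM(1,1) fit is undefined or numerically meaningless.

    Raised for flat series (development coefficient a -> 0, where the
    restored value b/a diverges), singular normal equations, and for
    diagnostics on a constant actual series (zero variance).
    """
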