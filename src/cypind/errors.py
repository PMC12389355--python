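"""Exception types shared across the package."""


class CypindError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CypindError, ValueError):
    """Raised when input data violate a documented precondition."""


class FitRefusedError(CypindError, ValueError):
    """Raised when a concentration-response fit cannot be attempted
    (for example fewer than four usable non-zero concentrations)."""


class NoCallError(CypindError, ValueError):
    """Raised when a calculation is requested for an enzyme whose induction
    was a no-call (maximum mean fold change below the 2-fold threshold).

    A no-call is deliberately distinct from "no induction" (R3 = 1): the
    parameters are not estimable, so downstream ratios are undefined rather
    than unity.
    """


class ValidationError(CypindError, ValueError):
    """Raised when a compound model or configuration fails validation."""
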