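"""Exception types shared across the package."""


class SiteLassoError(Exception):
    """Base class for all package-specific errors."""


class AlignmentFormatError(SiteLassoError, ValueError):
    """Raised when an alignment file cannot be parsed (ragged rows, empty file, ...)."""


class ValidationError(SiteLassoError, ValueError):
    """Raised when an input violates a documented precondition or invariant."""


class UnreachableFractionError(SiteLassoError, ValueError):
    """Raised when the requested site fraction zeta cannot be met anywhere on the
    Lasso penalty grid (it is bounded above by the fraction reached at the smallest
    penalty and below by the first point at which any coefficient activates)."""
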