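"""Exception types shared across the package."""


class MibciError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MibciError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(MibciError, ValueError):
    """Input data violates a documented precondition."""


class ParseError(MibciError, ValueError):
    """A trial file is malformed or internally inconsistent."""


class DegenerateInputError(MibciError, ValueError):
    """Numerically degenerate input (zero trace, zero variance, rank deficiency)."""


class ConvergenceError(MibciError, RuntimeError):
    """An iterative solver hit its iteration cap before reaching tolerance.

    Carries the best duality gap found in ``gap``.
    """

    def __init__(self, message: str, gap: float | None = None):
        super().__init__(message)
        self.gap = gap
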