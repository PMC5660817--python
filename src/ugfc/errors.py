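"""Exception hierarchy shared across the pipeline stages."""


class UGFCError(Exception):
    """Base class for all package errors."""


class InputDomainError(UGFCError, ValueError):
    """An intensity or array argument lies outside its valid domain."""


class ParameterError(UGFCError, ValueError):
    """A stage parameter violates its documented valid range."""


class ConfigError(ParameterError):
    """A pipeline configuration key is unknown or out of range."""


class DegenerateOutputError(UGFCError, ArithmeticError):
    """The aggregated fuzzy response is identically zero."""


class InitializationError(UGFCError, RuntimeError):
    """A stage cannot be initialized from the given input (degenerate data)."""


class SpecError(UGFCError, ValueError):
    """A phantom recipe is geometrically or statistically invalid."""


class NumericalError(UGFCError, FloatingPointError):
    """Non-finite values appeared during an iterative evolution."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class FormatError(UGFCError, ValueError):
    """An image file has an unsupported format or layout."""
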