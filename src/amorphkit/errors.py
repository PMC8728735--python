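"""Exception hierarchy shared across the pipeline."""


class AmorphkitError(Exception):
    """Base class for all package errors."""


class FormatError(AmorphkitError):
    """Structural problem in an input file (missing column, bad ordering)."""


class EmptyInputError(FormatError):
    """Input file contains no usable rows."""


class DomainError(AmorphkitError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class FitFailureError(AmorphkitError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NotFittableError(AmorphkitError):
    """The spectrum does not contain the feature the fit requires (e.g. a peak)."""


class InsufficientDataError(AmorphkitError):
    """Fewer data points than the operation's stated minimum."""


class InsufficientOverlapError(AmorphkitError):
    """Master-curve overlap region after shifting is below the minimum."""
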