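"""Exception hierarchy shared across the pipeline."""


class AneudoseError(Exception):
    """Base class for all package errors."""


class FormatError(AneudoseError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(AneudoseError, ValueError):
    """Input violates a documented invariant."""


class InsufficientDataError(AneudoseError):
    """Too few observations for the requested statistic."""


class GaussianFitError(AneudoseError):
    """Least-squares Gaussian fit failed to converge.

    Carries the initial parameter guess so the caller can retry or report.
    """

    def __init__(self, message: str, p0=None):
        super().__init__(message)
        self.p0 = p0


class UndefinedFdrError(AneudoseError):
    """FDR requested with zero observed flagged genes."""
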