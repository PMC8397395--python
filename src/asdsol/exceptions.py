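"""Exception hierarchy shared across the package."""


class AsdsolError(Exception):
    """Base class for all package errors."""


class ValidationError(AsdsolError, ValueError):
    """An input violates a documented precondition (shape, ordering, range)."""


class DomainError(AsdsolError, ValueError):
    """A mathematically valid input lies outside the model's domain
    (e.g. T <= T0 for the VFT law, Tg outside the Gordon-Taylor range)."""


class FitError(AsdsolError, RuntimeError):
    """A nonlinear fit failed to converge or is degenerate.

    Carries the last parameter iterate when available so callers can
    inspect where the optimizer stalled.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NoSolutionError(AsdsolError, RuntimeError):
    """A root-finding problem has no solution in the searched interval.

    ``scan_summary`` holds a diagnostic description of the scan performed.
    """

    def __init__(self, message, scan_summary=None):
        super().__init__(message)
        self.scan_summary = scan_summary


class DetectionError(AsdsolError, RuntimeError):
    """A feature-detection step (e.g. a heat-capacity step) found nothing
    above the noise floor."""


class PipelineError(AsdsolError, RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
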