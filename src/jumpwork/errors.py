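"""Exception hierarchy used across the package."""


class JumpworkError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(JumpworkError, ValueError):
    """A caller violated an operation precondition."""


class ValidationError(JumpworkError):
    """A trial or time series violates its structural invariants."""


class FormatError(JumpworkError):
    """An on-disk trial does not conform to the documented format."""


class EventDetectionError(JumpworkError):
    """Phase events (onset/contact/takeoff) could not be located."""


class SimulationError(JumpworkError):
    """Forward simulation diverged or produced a non-finite state."""

    def __init__(self, message: str, phase: str | None = None):
        super().__init__(message if phase is None else f"{message} (phase: {phase})")
        self.phase = phase


class AnalysisError(JumpworkError):
    """A statistical analysis could not be carried out as requested."""
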