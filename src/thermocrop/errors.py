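"""Exception hierarchy for the thermocrop pipeline."""


class ThermocropError(Exception):
    """Base class for all thermocrop errors."""


class RadiometricDomainError(ThermocropError, ValueError):
    """A raw count or temperature falls outside the calibration model's domain."""


class RegistrationError(ThermocropError, ValueError):
    """Control-point fitting failed or a window falls outside the frame."""


class SingularFitError(RegistrationError):
    """Control points are degenerate (no spread along a fitted axis)."""


class WindowOutOfBoundsError(RegistrationError):
    """The thermal overlap window does not fit inside the scaled visible frame."""


class NoCanopyError(ThermocropError, ValueError):
    """The refined canopy mask is empty: no canopy detected."""


class InvalidReferencesError(ThermocropError, ValueError):
    """Wet/dry reference temperatures do not satisfy T_dry > T_wet."""


class RoiError(ThermocropError, ValueError):
    """A region of interest is empty or out of frame bounds."""


class PipelineStageError(ThermocropError, RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")


class SidecarSchemaError(ThermocropError, ValueError):
    """A metadata sidecar is missing required keys or has invalid values."""


class DimensionMismatchError(ThermocropError, ValueError):
    """An image does not have the dimensions its role requires."""


class MalformedFileError(ThermocropError, ValueError):
    """A file could not be parsed at all (bad JSON, bad image container)."""
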