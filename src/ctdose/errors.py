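"""Exception hierarchy for ctdose."""


class CTDoseError(Exception):
    """Base class for all ctdose errors."""


class DomainError(CTDoseError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class CommissioningError(CTDoseError):
    """Commissioning data violate a beam-model invariant."""


class ConfigurationError(CTDoseError):
    """Inconsistent or unsupported configuration (technique, table, params)."""


class CalibrationError(CTDoseError):
    """Absolute calibration cannot be anchored (e.g. zero dose at isocenter)."""


class NormalizationError(CTDoseError):
    """A relative dose distribution cannot be normalized (all-zero field)."""


class FormatError(CTDoseError):
    """A file on disk does not conform to the expected format."""


class PipelineError(CTDoseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
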