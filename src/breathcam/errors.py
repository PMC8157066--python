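"""Domain-specific exceptions raised by the respiration pipeline."""


class BreathcamError(Exception):
    """Base class for all breathcam errors."""


class NoROIError(BreathcamError):
    """No respiration-carrying pixels were detected in a window."""


class NoSymmetryError(BreathcamError):
    """No pair of origin-symmetric clusters exists (window unmeasurable)."""


class NoBreathDetectedError(BreathcamError):
    """Fewer than two breath peaks found; bpm is undefined (e.g. apnea)."""
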