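"""Exception hierarchy for armcall."""


class ArmcallError(Exception):
    """Base class for all armcall errors."""


class UnknownChromosomeError(ArmcallError):
    """A chromosome name is not part of the genome model."""


class ValidationError(ArmcallError):
    """An input table violates a structural invariant."""


class CallingError(ArmcallError):
    """Aberration calling could not be performed."""


class SegmentationError(ArmcallError):
    """Segmentation preconditions not met."""
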