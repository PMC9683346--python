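"""Exception hierarchy for the qfadd pipeline."""


class QFADDError(Exception):
    """Base class for all qfadd-specific errors."""


class ValidationError(QFADDError, ValueError):
    """Input violates a documented precondition."""


class FormatError(QFADDError, ValueError):
    """A file was readable but its layout does not match the expected format."""


class StackIOError(QFADDError, IOError):
    """A file could not be read or written."""


class SegmentationError(QFADDError):
    """Nuclear segmentation failed (blank field, ambiguous components, ...)."""


class NormalizationError(QFADDError):
    """A normalization denominator is zero or otherwise unusable."""


class CoverageError(QFADDError):
    """Simulated trajectory does not span the experimental time window."""
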