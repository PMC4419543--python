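"""Exception and warning types used across the pipeline."""


class SliceThickError(Exception):
    """Base class for all slicethick errors."""


class ValidationError(SliceThickError, ValueError):
    """Invalid parameter or malformed input value."""


class DecodeError(SliceThickError, IOError):
    """An image file could not be read or decoded."""


class DegenerateThresholdError(SliceThickError):
    """Automatic thresholding cannot separate two classes (constant image)."""


class OrientationAmbiguityError(SliceThickError):
    """Foreground polarity cannot be decided (exact 50/50 mask) and no
    override was given."""


class AxisAmbiguityError(SliceThickError):
    """Principal axis of the foreground is undefined (isotropic blob)."""


class EmptySegmentWarning(UserWarning):
    """A measurement segment contained no foreground; its thickness is 0."""


class IrregularSliceWarning(UserWarning):
    """Coefficient of variation across segments exceeded the 0.25 QC bound."""
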