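"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ImageFormatError(ValidationError):
    """Image file exists but is not a single-channel 2D image."""


class UndefinedMetricError(RuntimeError):
    """A metric is undefined for this input (e.g. empty skeleton)."""


class SnapshotIrregularityError(RuntimeError):
    """Segmentation produced no usable structure; snapshot must be excluded."""
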