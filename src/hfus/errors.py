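"""Exception hierarchy for the HFUS quantification pipeline."""


class HfusError(Exception):
    """Base class for all pipeline errors."""


class FormatError(HfusError):
    """An input file decodes but does not satisfy the expected format."""


class CalibrationError(HfusError):
    """Pixel-size estimation from the ruler failed."""


class SegmentationError(HfusError):
    """Entry-echo segmentation produced no usable layer."""


class GeometryError(HfusError):
    """ROI construction is impossible for the given boundary."""


class MeasurementError(HfusError):
    """A skin parameter cannot be computed (e.g. empty ROI)."""


class ManifestError(HfusError):
    """Study manifest metadata is inconsistent."""
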