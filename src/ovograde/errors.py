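"""Exception hierarchy shared by all pipeline stages."""


class OvogradeError(Exception):
    """Base class for all ovograde errors."""


class ImageIOError(OvogradeError):
    """A file could not be read or decoded; the message names the path."""


class DegenerateImageError(OvogradeError):
    """An operation received an image without enough structure to act on
    (e.g. thresholding a constant image)."""


class SegmentationError(OvogradeError):
    """A segmentation stage produced an empty or unusable region."""


class ValidationError(OvogradeError, ValueError):
    """An argument violated a precondition (shape, range, unit convention)."""
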