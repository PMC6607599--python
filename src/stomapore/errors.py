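"""Exception hierarchy for the stomapore pipeline.

Every stage failure maps to one of these; the pipeline catches
:class:`StomaporeError` and records the failing stage instead of raising.
"""


class StomaporeError(Exception):
    """Base class for all stomapore-specific failures."""


class InvalidArgumentError(StomaporeError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateLevelSetError(StomaporeError):
    """The level set has collapsed to a single sign (no contour left)."""


class EmptySegmentationError(StomaporeError):
    """Segmentation produced no usable foreground region."""


class DisconnectFailedError(StomaporeError):
    """Morphological disconnection eroded the region away entirely."""


class TooSmallRegionError(StomaporeError):
    """Region is below the minimum size for boundary/moment analysis."""


class FitFailedError(StomaporeError):
    """Conic fit is under-determined or did not yield an ellipse."""
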