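"""Exception hierarchy for fivedpet."""


class FiveDPetError(Exception):
    """Base class for all fivedpet errors."""


class DomainError(FiveDPetError, ValueError):
    """A parameter is outside its physical or mathematical domain."""


class CoverageError(FiveDPetError, ValueError):
    """A time grid does not cover the span required by a frame schedule."""


class ShapeError(FiveDPetError, ValueError):
    """Array dimensions are inconsistent with the declared geometry."""


class CompletenessError(FiveDPetError, ValueError):
    """A (frame, gate) collection is missing entries or has duplicates."""


class WindowError(FiveDPetError, ValueError):
    """A summation window selects no frames."""


class SegmentationError(FiveDPetError, RuntimeError):
    """Cavity segmentation produced an empty mask."""


class UndefinedMetricError(FiveDPetError, ZeroDivisionError):
    """A ratio metric (e.g. LVEF) is undefined because its denominator is zero."""


class FormatError(FiveDPetError, ValueError):
    """An on-disk artifact is inconsistent (e.g. sidecar/frame-count mismatch)."""


class GeometryError(FiveDPetError, ValueError):
    """Phantom geometry does not fit inside the voxel grid."""
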