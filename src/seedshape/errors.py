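"""Exception hierarchy shared across the toolkit."""


class SeedShapeError(Exception):
    """Base class for all seedshape errors."""


class SegmentationError(SeedShapeError):
    """Binarization could not separate foreground from background."""


class EmptyResultError(SeedShapeError):
    """No silhouette satisfied the extraction criteria."""


class DegenerateRegionError(SeedShapeError):
    """A region is collinear, empty, or otherwise has no usable geometry."""


class InvalidMeasurementError(SeedShapeError, ValueError):
    """A scalar measurement violates its precondition (e.g. W <= 0)."""


class InvalidGeometryError(SeedShapeError, ValueError):
    """A polygon input is self-intersecting or otherwise invalid."""
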