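"""Exception types raised by corneafit."""


class CorneaFitError(Exception):
    """Base class for all corneafit errors."""


class GridParseError(CorneaFitError):
    """A polar elevation CSV could not be parsed as a numeric table."""


class GridDimensionError(CorneaFitError):
    """A polar elevation table has the wrong shape."""


class EmptyCloudError(CorneaFitError):
    """All grid cells are sentinel-coded; no point cloud can be formed."""


class InsufficientDataError(CorneaFitError):
    """Fewer points than the minimum required by a fitter (10)."""


class DegenerateCloudError(CorneaFitError):
    """The point cloud does not constrain a unique quadric (rank-deficient design)."""


class NotAnEllipsoidError(CorneaFitError):
    """The quadric's signature is not that of a real ellipsoid."""


class SurfaceMissError(CorneaFitError):
    """The fitted surface has no real elevation at any data node."""


class FootprintError(CorneaFitError):
    """Mesh export footprint extends beyond the surface's xy-extent."""
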