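"""Exception hierarchy used across the package."""


class LigafemError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(LigafemError):
    """Invalid or inconsistent model geometry (e.g. overlapping prisms)."""


class CapacityError(GeometryError):
    """Requested elastin block count or content exceeds the placement lattice."""


class ContentUndefinedError(LigafemError):
    """Elastin content is undefined for this model kind (e.g. the sheet model)."""


class MeshingError(LigafemError):
    """Voxelization failure, typically a spacing that does not divide the geometry."""


class MaterialError(LigafemError):
    """Invalid material constants (E <= 0 or Poisson ratio outside [0, 0.5))."""


class UnderConstrainedError(LigafemError):
    """The constrained stiffness matrix is singular (rigid-body modes remain)."""


class ProtocolError(LigafemError):
    """A loading protocol cannot be applied to the given model (missing bone etc.)."""


class QueryError(LigafemError):
    """A summary/metrics query over an empty or unknown component."""


class ComparisonError(LigafemError):
    """Model comparison requested between rows that are not both present."""


class ImageError(LigafemError):
    """Undefined content estimate or impossible synthetic-image request."""
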