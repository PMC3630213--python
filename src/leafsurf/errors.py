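"""Exception hierarchy.

Every error raised on bad input or failed computation derives from
:class:`LeafSurfError`, so callers (and the CLI) can catch one type.
"""


class LeafSurfError(Exception):
    """Base class for all leafsurf errors."""


class DimensionError(LeafSurfError):
    """Array shapes do not match the operation's contract."""


class InputError(LeafSurfError):
    """Input is structurally invalid (too few items, empty region, ...)."""


class CalibrationError(LeafSurfError):
    """Physical calibration is degenerate (e.g. zero axial extent)."""


class DegenerateInputError(LeafSurfError):
    """Input carries no usable signal (e.g. constant image for Otsu)."""


class SegmentationError(LeafSurfError):
    """Leaf segmentation produced an empty or invalid mask."""


class GeometryError(LeafSurfError):
    """Geometric precondition violated (collinear points, bad polygon)."""


class FitError(LeafSurfError):
    """Elastic-map fitting failed (singular system, empty nodes)."""


class DomainError(LeafSurfError):
    """Query point outside the fitted surface's domain."""


class MeshError(LeafSurfError):
    """Surface mesh is degenerate (zero-area triangles, ...)."""


class UnreachableError(LeafSurfError):
    """Geodesic target not reachable (disconnected mesh)."""


class SchemaError(LeafSurfError):
    """Annotation file violates the expected schema."""


class FrameError(LeafSurfError):
    """Leaf coordinate frame is degenerate."""


class SamplingError(LeafSurfError):
    """Synthetic point-pattern sampling infeasible under constraints."""


class CoverageError(LeafSurfError):
    """Synthetic z-range does not cover the ground-truth surface."""
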