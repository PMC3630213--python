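"""Leaf segmentation: Otsu threshold + disc opening, or a manual polygon.

Bright-field leaves are darker than the background, so the default
foreground is the below-threshold class.  Morphological opening with a
disc larger than the broadest trichome erases trichomes protruding past
the leaf outline (the erosion deletes them, the dilation rebuilds the
lamina), and hole filling repairs punctures left where trichome stalks
cross the leaf edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, GeometryError, SegmentationError

__all__ = ["LeafMask", "otsu_threshold", "segment_leaf", "manual_leaf_polygon"]


@dataclass
class LeafMask:
    """Binary leaf region with its traced boundary polygon.

    The boundary is an ordered closed polygon in (x, y) pixel coordinates
    (pixel-centered, 0-based).
    """

    mask: np.ndarray
    boundary: np.ndarray = field(repr=False)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def polygon(self) -> Polygon:
        """Boundary as a shapely polygon (x, y pixel coordinates)."""
        return Polygon(self.boundary)


def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance of the gray histogram."""
    img = np.asarray(img, dtype=np.float64)
    if np.unique(img).size < 2:
        raise DegenerateInputError("image is constant; Otsu threshold undefined")
    return float(threshold_otsu(img, nbins=n_bins))


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Closed sub-pixel contour of the mask, as (x, y) vertices."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("mask has no traceable boundary")
    longest = max(contours, key=len)  # outer contour of the single component
    return longest[:, ::-1].copy()  # (row, col) -> (x, y)


def segment_leaf(
    img: np.ndarray,
    disc_radius_px: int = 25,
    foreground: str = "dark",
    n_bins: int = 256,
    fill_holes: bool = True,
) -> LeafMask:
    """Segment the leaf from a sharpened composite image.

    Otsu-threshold, keep the largest connected component of the foreground
    class ("dark" or "light" relative to the threshold), open with a disc
    structuring element of ``disc_radius_px``, fill holes (trichome stalks
    crossing the leaf edge otherwise puncture the mask; disable with
    ``fill_holes=False`` for a strictly anti-extensive mask), and trace the
    boundary.
    """
    if disc_radius_px < 1:
        raise ValueError(f"disc_radius_px must be >= 1, got {disc_radius_px}")
    if foreground not in ("dark", "light"):
        raise ValueError(f"foreground must be 'dark' or 'light', got {foreground!r}")
    t = otsu_threshold(img, n_bins=n_bins)
    fg = img < t if foreground == "dark" else img > t
    if not fg.any():
        raise SegmentationError("no foreground pixels after thresholding")
    labels, n = ndimage.label(fg)
    largest = labels == (np.bincount(labels.ravel())[1:].argmax() + 1)
    opened = morphology.opening(largest, morphology.disk(disc_radius_px))
    if not opened.any():
        raise SegmentationError(
            f"foreground vanished after opening with disc radius {disc_radius_px}"
        )
    # opening can split the component; keep the largest piece again
    labels, n = ndimage.label(opened)
    if n > 1:
        opened = labels == (np.bincount(labels.ravel())[1:].argmax() + 1)
    final = ndimage.binary_fill_holes(opened) if fill_holes else opened
    return LeafMask(mask=final, boundary=_trace_boundary(final))


def manual_leaf_polygon(
    points: np.ndarray, shape: tuple[int, int] | None = None
) -> LeafMask:
    """Leaf mask from a hand-drawn outline: rasterized convex hull.

    ``points`` is an (N, 2) array of (x, y) pixel positions.  A pixel
    belongs to the mask if its center lies inside or on the hull boundary.
    ``shape`` (H, W) defaults to the hull's bounding box.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[0] < 3 or points.shape[1] != 2:
        raise GeometryError(f"need >= 3 (x, y) points, got array of shape {points.shape}")
    try:
        hull = ConvexHull(points)
    except QhullError as e:
        raise GeometryError(f"points are collinear or degenerate: {e}") from e
    verts = points[hull.vertices]
    poly = Polygon(verts)
    if shape is None:
        h = int(np.ceil(points[:, 1].max())) + 1
        w = int(np.ceil(points[:, 0].max())) + 1
        shape = (h, w)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    centers = shapely.points(xx.ravel().astype(float), yy.ravel().astype(float))
    inside = shapely.covers(poly, centers).reshape(shape)
    closed = np.vstack([verts, verts[:1]])
    return LeafMask(mask=inside, boundary=closed)
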