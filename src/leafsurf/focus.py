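"""Shape-from-focus: Sobel sharpness, height-map extraction, sharp composite.

Each surface point is in focus in the slice whose focal plane matches its
height, and in-focus regions show the strongest local edges.  The per-pixel
sharpness measure is the magnitude of the 3x3 Sobel gradient; a pixel's
height is the slice index maximizing that sharpness over a small spatial
window (default 5x5) around the pixel.  Picking, per pixel, the intensity
of its best-focus slice yields an extended-depth-of-field 2D composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError
from .stackio import ImageStack

__all__ = [
    "HeightMap",
    "sobel_sharpness",
    "compute_height_map",
    "compose_sharp_image",
]

#: aggregate sharpness below this (on [0,1]-normalized stacks) marks a pixel
#: as textureless; its height is filled from the nearest textured pixel
TEXTURELESS_EPS = 1e-6


@dataclass
class HeightMap:
    """Per-pixel best-focus z position.

    ``z_index`` holds slice indices; ``um_per_slice`` scales them to µm.
    ``textured`` flags pixels whose height came from actual sharpness
    signal rather than nearest-neighbor fill.
    """

    z_index: np.ndarray
    um_per_slice: float = 1.0
    textured: np.ndarray | None = None

    @property
    def z_um(self) -> np.ndarray:
        return self.z_index.astype(np.float64) * self.um_per_slice

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_index.shape


def sobel_sharpness(stack: ImageStack) -> np.ndarray:
    """Per-slice Sobel gradient magnitude, shape (n_slices, H, W).

    Uses the standard 3x3 Sobel pair; magnitude is the Euclidean norm of
    the horizontal and vertical responses.  Borders are edge-replicated to
    avoid spurious gradient maxima at the image frame.
    """
    out = np.empty_like(stack.data)
    for k in range(stack.n_slices):
        gy = ndimage.sobel(stack.data[k], axis=0, mode="nearest")
        gx = ndimage.sobel(stack.data[k], axis=1, mode="nearest")
        out[k] = np.hypot(gx, gy)
    return out


def _aggregate_sharpness(sharp: np.ndarray, window: int) -> np.ndarray:
    """Max-filter each slice's sharpness over a window x window neighborhood."""
    out = np.empty_like(sharp)
    for k in range(sharp.shape[0]):
        out[k] = ndimage.maximum_filter(sharp[k], size=window, mode="nearest")
    return out


def compute_height_map(
    stack: ImageStack,
    window: int = 5,
    um_per_slice: float = 1.0,
    textureless_eps: float = TEXTURELESS_EPS,
) -> HeightMap:
    """Best-focus slice index per pixel.

    A pixel is considered sharp in slice k if its Sobel magnitude, or the
    Sobel magnitude anywhere within the ``window`` x ``window`` neighborhood,
    reaches its maximum over z in slice k.  Ties are broken toward the
    lowest slice index (argmax convention), which keeps the output
    deterministic and stable under slice-order perturbations.

    Pixels with no sharpness signal in any slice (aggregate below
    ``textureless_eps``) take the height of their nearest textured pixel.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    agg = _aggregate_sharpness(sobel_sharpness(stack), window)
    z_index = np.argmax(agg, axis=0)
    textured = agg.max(axis=0) >= textureless_eps
    if not textured.all() and textured.any():
        # nearest-neighbor fill of textureless pixels
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~textured, return_indices=True
        )
        z_index = z_index[iy, ix]
    return HeightMap(z_index=z_index, um_per_slice=um_per_slice, textured=textured)


def compose_sharp_image(stack: ImageStack, hm: HeightMap) -> np.ndarray:
    """Extended-depth-of-field composite: out(y,x) = stack(y, x, z_index(y,x))."""
    if hm.shape != stack.shape:
        raise DimensionError(
            f"height map shape {hm.shape} does not match stack shape {stack.shape}"
        )
    return np.take_along_axis(stack.data, hm.z_index[None, :, :], axis=0)[0]
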