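"""Image-stack I/O and physical calibration.

A focus stack is a series of grayscale images of the same scene acquired at
successive focal depths.  Intensities are min-max normalized per stack to
[0, 1]; sharpness comparisons are within-stack only, so the absolute
intensity scale carries no information.

The axial scale (µm per z-slice) is derived from a reference object of
known thickness placed next to the specimen: the number of slices between
the two faces of the reference being in focus spans its physical thickness.
Lateral scale (µm per pixel) is a user-supplied configuration value.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import CalibrationError, DimensionError, InputError

__all__ = [
    "ImageStack",
    "Calibration",
    "read_stack",
    "write_stack",
    "calibrate_z",
]


@dataclass(frozen=True)
class Calibration:
    """Physical scale of a stack: lateral µm/pixel and axial µm/slice."""

    um_per_px: float
    um_per_slice: float

    def __post_init__(self) -> None:
        for name in ("um_per_px", "um_per_slice"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CalibrationError(f"{name} must be positive and finite, got {v!r}")


class ImageStack:
    """A calibrated z-stack of grayscale images.

    Parameters
    ----------
    data
        Array of shape (n_slices, H, W).  Normalized to [0, 1] on
        construction unless already in range and ``normalize=False``.
    """

    def __init__(self, data: np.ndarray, normalize: bool = True):
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3:
            raise DimensionError(f"stack must be 3D (z, H, W), got shape {data.shape}")
        if data.shape[0] < 2:
            raise InputError(f"a stack needs at least 2 slices, got {data.shape[0]}")
        if not np.all(np.isfinite(data)):
            raise InputError("stack contains non-finite intensities")
        if normalize:
            lo, hi = data.min(), data.max()
            data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
        self.data = data

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of each slice."""
        return self.data.shape[1:]

    def slice(self, k: int) -> np.ndarray:
        return self.data[k]


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Collapse RGB(A) to grayscale by luminance average of the color channels."""
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return np.asarray(img, dtype=np.float64)


def read_stack(source: str | os.PathLike | Sequence[str | os.PathLike]) -> ImageStack:
    """Read a focus stack from a multi-page TIFF or an ordered image series.

    A single path is treated as a multi-page TIFF; a sequence of paths is
    read in the given order (sort lexicographically beforehand if needed).
    RGB inputs are converted to grayscale; intensities are min-max
    normalized per stack.
    """
    if isinstance(source, (str, os.PathLike)):
        arr = tifffile.imread(str(source))
        if arr.ndim == 2:
            raise InputError(f"{source} holds a single image; a stack needs >= 2 slices")
        if arr.ndim == 4:  # multipage RGB
            arr = arr[..., :3].mean(axis=-1)
        slices = [np.asarray(s, dtype=np.float64) for s in arr]
    else:
        paths = list(source)
        if len(paths) < 2:
            raise InputError(f"a stack needs at least 2 images, got {len(paths)}")
        slices = [_to_gray(iio.imread(str(p))) for p in paths]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise DimensionError(f"slices have mismatched dimensions: {sorted(shapes)}")
    return ImageStack(np.stack(slices, axis=0))


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write a stack as a 16-bit multi-page TIFF.

    Values are quantized to the 16-bit grid; a read→write→read cycle is
    lossless once values lie on that grid (as they do for any stack read
    from an 8/16-bit file).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.rint(stack.data * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def calibrate_z(ref_thickness_um: float, idx_bottom: int, idx_top: int) -> float:
    """Axial scale from a reference object of known thickness.

    ``idx_bottom`` and ``idx_top`` are the stack indices at which the
    reference's bottom/top faces are in sharpest focus; the order of the
    two is irrelevant.

    Returns µm per z-slice = ref_thickness_um / |idx_top - idx_bottom|.
    """
    if not np.isfinite(ref_thickness_um) or ref_thickness_um <= 0:
        raise CalibrationError(f"reference thickness must be positive, got {ref_thickness_um!r}")
    if idx_top == idx_bottom:
        raise CalibrationError(
            "reference top/bottom focus indices are equal: zero axial extent"
        )
    return float(ref_thickness_um) / abs(int(idx_top) - int(idx_bottom))
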