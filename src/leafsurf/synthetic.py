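"""Synthetic scenes with known ground truth for every pipeline stage.

A scene is a textured surface z = h(x, y) imaged through an idealized
defocus model: a slice focused at depth z blurs each pixel with a Gaussian
of width sigma(z) = sigma0 + k * |z - h(x, y)|, the simplest monotone model
under which argmax-of-sharpness recovers h.  Texture is band-limited
uniform noise at a set contrast; the leaf region is darker than the
constant background, matching bright-field appearance, and the constant
background exercises the textureless-fill path of the height map.

Trichome patterns are drawn from a hard-core (minimum-distance) point
process inside the mask, with developmental classes assigned by
longitudinal zones — mature trichomes toward the tip, initiation sites
toward the base — with an adjustable overlap between zones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CoverageError, InputError, SamplingError
from .focus import HeightMap
from .patterning import LeafFrame, Trichome, to_frame
from .segmentation import LeafMask, _trace_boundary
from .stackio import ImageStack
from .surface import ElasticMap, SurfaceMesh

__all__ = [
    "SyntheticScene",
    "render_stack",
    "sample_pattern",
    "ellipse_mask",
    "heightfield_mesh",
    "sphere_cap_mesh",
    "analytic_map",
]


def ellipse_mask(shape: tuple[int, int], rx_frac: float = 0.38, ry_frac: float = 0.42) -> LeafMask:
    """Centered elliptical leaf mask covering the given image shape."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    m = ((xx - cx) / (rx_frac * w)) ** 2 + ((yy - cy) / (ry_frac * h)) ** 2 <= 1.0
    return LeafMask(mask=m, boundary=_trace_boundary(m))


@dataclass
class SyntheticScene:
    """A stated imaging scene: surface family, texture, defocus, mask, seed.

    Heights are in slice units over pixel coordinates.  ``amplitude`` is
    the surface relief in slices; defaults describe a gently domed young
    leaf spanning most of a 60-slice stack.
    """

    shape: tuple[int, int] = (200, 200)
    surface: str = "gaussian_bump"
    amplitude: float = 40.0
    base: float = 8.0
    bump_width_frac: float = 0.35
    tilt: tuple[float, float] = (0.1, 0.15)
    sigma0: float = 0.5
    k: float = 0.3
    contrast: float = 0.5
    mask_shape: str = "ellipse"
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.k <= 0:
            raise InputError("need sigma0 >= 0 and k > 0")

    def height(self) -> np.ndarray:
        """Ground-truth surface h(x, y) in slice units."""
        h, w = self.shape
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        if self.surface == "plane":
            return np.full(self.shape, self.base + self.amplitude / 2.0)
        if self.surface == "tilted_plane":
            ax, ay = self.tilt
            z = ax * (xx - cx) + ay * (yy - cy)
            z = (z - z.min()) / max(np.ptp(z), 1e-12) * self.amplitude
            return self.base + z
        if self.surface == "gaussian_bump":
            wdt = self.bump_width_frac * min(h, w)
            return self.base + self.amplitude * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * wdt**2)
            )
        if self.surface == "cylinder":
            r = 0.75 * w
            return self.base + self.amplitude * np.sqrt(
                np.clip(1.0 - ((xx - cx) / r) ** 2, 0.0, None)
            )
        if self.surface == "hemisphere_cap":
            r = 0.75 * min(h, w)
            return self.base + self.amplitude * np.sqrt(
                np.clip(1.0 - ((xx - cx) ** 2 + (yy - cy) ** 2) / r**2, 0.0, None)
            )
        raise InputError(f"unknown surface family {self.surface!r}")

    def mask(self) -> LeafMask:
        if self.mask_shape == "ellipse":
            return ellipse_mask(self.shape)
        if self.mask_shape == "none":
            m = np.ones(self.shape, dtype=bool)
            h, w = self.shape
            boundary = np.array([[0, 0], [w - 1.0, 0], [w - 1.0, h - 1.0], [0, h - 1.0], [0, 0]])
            return LeafMask(mask=m, boundary=boundary)
        raise InputError(f"unknown mask shape {self.mask_shape!r}")

    def texture(self) -> np.ndarray:
        """Band-limited noise texture; leaf darker than the background."""
        rng = np.random.default_rng(self.seed)
        noise = ndimage.gaussian_filter(rng.uniform(size=self.shape), 1.2)
        lo, hi = noise.min(), noise.max()
        t = (noise - lo) / max(hi - lo, 1e-12)
        img = np.full(self.shape, 0.9)
        m = self.mask().mask
        img[m] = 0.2 + 0.5 * self.contrast * t[m]
        return img


def render_stack(scene: SyntheticScene, n_slices: int = 60) -> tuple[ImageStack, HeightMap]:
    """Render a focus stack and the true height map for the scene.

    The slice focused at index i blurs pixel p with a Gaussian of
    sigma = sigma0 + k * |i - h(p)|, approximated by linear interpolation
    within a precomputed bank of uniformly blurred textures.
    """
    if n_slices < 2:
        raise InputError(f"need >= 2 slices, got {n_slices}")
    h = scene.height()
    if h.min() < 0 or h.max() > n_slices - 1:
        raise CoverageError(
            f"surface range [{h.min():.2f}, {h.max():.2f}] not covered by "
            f"slice range [0, {n_slices - 1}]"
        )
    tex = scene.texture()
    step = 0.5
    sigma_max = scene.sigma0 + scene.k * (n_slices - 1)
    levels = np.arange(0.0, sigma_max + step, step)
    bank = np.stack(
        [tex if s == 0 else ndimage.gaussian_filter(tex, s) for s in levels]
    )
    hh, ww = scene.shape
    iy, ix = np.mgrid[0:hh, 0:ww]
    slices = np.empty((n_slices, hh, ww))
    for i in range(n_slices):
        sigma = scene.sigma0 + scene.k * np.abs(i - h)
        pos = np.clip(sigma / step, 0, len(levels) - 1 - 1e-9)
        lo = pos.astype(np.int64)
        frac = pos - lo
        slices[i] = bank[lo, iy, ix] * (1 - frac) + bank[lo + 1, iy, ix] * frac
    truth = HeightMap(z_index=h, um_per_slice=1.0)
    return ImageStack(slices), truth


def sample_pattern(
    mask: LeafMask,
    n_per_class: tuple[int, int, int, int] = (6, 5, 4, 3),
    min_spacing: float = 0.0,
    seed: int = 0,
    zone_overlap: float = 0.25,
    um_per_px: float = 1.0,
    max_tries: int = 200_000,
) -> tuple[list, LeafFrame]:
    """Hard-core trichome pattern with longitudinal class zones.

    Classes occupy bands along the normalized leaf axis — class 1
    (initiation) nearest the base, class 4 (mature) nearest the tip — each
    band widened by ``zone_overlap`` on both sides (0 = fully separated
    zones).  ``min_spacing`` is the minimum pairwise distance in µm.
    Returns (trichomes, frame); the frame runs from the mask's basal edge
    (image bottom) to its tip (image top).
    """
    if len(n_per_class) != 4 or any(n < 0 for n in n_per_class):
        raise InputError("n_per_class must be four non-negative counts")
    rng = np.random.default_rng(seed)
    yy, xx = np.nonzero(mask.mask)
    y_bot, y_top = yy.max(), yy.min()
    origin_px = np.array([xx[yy == y_bot].mean(), float(y_bot)])
    tip_px = np.array([xx[yy == y_top].mean(), float(y_top)])
    frame = LeafFrame(origin_um=origin_px * um_per_px, tip_um=tip_px * um_per_px)
    coords = np.column_stack([xx, yy]).astype(np.float64)
    accepted_xy: list[np.ndarray] = []
    trichomes: list[Trichome] = []
    tries = 0
    for cls_idx, count in enumerate(n_per_class):
        c = cls_idx + 1
        lo = max(0.0, (c - 1) / 4.0 - zone_overlap)
        hi = min(1.0, c / 4.0 + zone_overlap)
        placed = 0
        while placed < count:
            tries += 1
            if tries > max_tries:
                raise SamplingError(
                    f"could not place {count} class-{c} points with spacing "
                    f"{min_spacing} within {max_tries} tries"
                )
            p = coords[rng.integers(len(coords))] + rng.uniform(-0.5, 0.5, size=2)
            p_um = p * um_per_px
            ynorm = to_frame(p_um, frame)[1]
            if not (lo <= ynorm <= hi):
                continue
            if min_spacing > 0 and accepted_xy:
                d = np.linalg.norm(np.asarray(accepted_xy) - p_um, axis=1)
                if d.min() < min_spacing:
                    continue
            accepted_xy.append(p_um)
            trichomes.append(
                Trichome(id=f"t{len(trichomes):04d}", xy_px=p, cls=c)
            )
            placed += 1
    return trichomes, frame


# ---------------------------------------------------------------------------
# analytic fixture surfaces
# ---------------------------------------------------------------------------


def heightfield_mesh(
    f, x_range, y_range, shape: tuple[int, int], mask: np.ndarray | None = None
) -> SurfaceMesh:
    """Grid mesh of z = f(x, y) over a rectangle (fixture surfaces)."""
    n, m = shape
    gx = np.linspace(*x_range, m)
    gy = np.linspace(*y_range, n)
    X, Y = np.meshgrid(gx, gy)
    return SurfaceMesh.from_grid(X, Y, f(X, Y), mask=mask)


def sphere_cap_mesh(
    radius: float, colat_max: float = np.pi / 2, n_theta: int = 200, n_phi: int = 200
) -> SurfaceMesh:
    """Spherical cap meshed on a (colatitude, longitude) grid.

    The pole is closed by a triangle fan to an apex vertex, so all
    triangles are non-degenerate.  ``colat_max`` = pi/2 gives the full
    hemisphere (area 2*pi*r^2).
    """
    thetas = colat_max * np.arange(1, n_theta + 1) / n_theta
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    T, P = np.meshgrid(thetas, phis, indexing="ij")
    verts = [np.array([[0.0, 0.0, radius]])]
    ring = np.stack(
        [
            radius * np.sin(T) * np.cos(P),
            radius * np.sin(T) * np.sin(P),
            radius * np.cos(T),
        ],
        axis=-1,
    ).reshape(-1, 3)
    verts.append(ring)
    vertices = np.vstack(verts)

    def vid(i, j):  # ring i (0-based), longitude j
        return 1 + i * n_phi + (j % n_phi)

    tris = []
    for j in range(n_phi):
        tris.append([0, vid(0, j), vid(0, j + 1)])
    for i in range(n_theta - 1):
        for j in range(n_phi):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            tris.append([a, b, d])
            tris.append([a, d, c])
    return SurfaceMesh(vertices, np.asarray(tris, dtype=np.int64))


def analytic_map(f, x_range, y_range, grid_shape: tuple[int, int] = (30, 30)) -> ElasticMap:
    """Elastic map whose nodes sample z = f(x, y) on a regular grid."""
    n, m = grid_shape
    gx = np.linspace(*x_range, m)
    gy = np.linspace(*y_range, n)
    X, Y = np.meshgrid(gx, gy)
    return ElasticMap(nodes=np.stack([X, Y, f(X, Y)], axis=-1))
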