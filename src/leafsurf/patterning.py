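"""Trichome annotations, leaf frames, meta-leaf pooling and genotype tests.

Trichomes are classed by developmental stage: 1 = initiation (unbranched),
2 = two branches, 3 = three branches, 4 = mature (incrusted cell wall).
Leaves are comparable only at similar stages, so only leaves carrying one
to six mature trichomes enter the analysis.

Each leaf carries an orthogonal coordinate frame: the origin sits in the
middle of the petiole at the lamina's base, the y-axis points along the
longitudinal axis with the tip point at unit length, and the x-axis is the
perpendicular with the same scale.  Mapping all leaves of a genotype into
this frame pools them into a "meta leaf", on which class-stratified spatial
statistics are computed and compared between genotypes with two-sided
Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Polygon

from . import geometry
from .errors import FrameError, InputError, SchemaError
from .segmentation import LeafMask
from .stackio import Calibration
from .surface import ElasticMap, SurfaceMesh, evaluate_surface, triangulate

__all__ = [
    "Trichome",
    "LeafFrame",
    "Leaf",
    "MetaLeaf",
    "CLASSES",
    "load_annotations",
    "write_annotations",
    "select_leaf",
    "to_frame",
    "build_metaleaf",
    "longitudinal_profile",
    "metaleaf_histogram",
    "base_distance",
    "density",
    "class_abundance",
    "leaf_morphometrics",
    "wilcoxon_ranksum",
    "genotype_statistics",
    "compare_genotypes",
]

CLASSES = (1, 2, 3, 4)
CLASS_NAMES = {1: "initiation", 2: "two-branch", 3: "three-branch", 4: "mature"}


@dataclass
class Trichome:
    """An annotated trichome: image position plus developmental class."""

    id: str
    xy_px: np.ndarray
    cls: int

    def __post_init__(self) -> None:
        self.xy_px = np.asarray(self.xy_px, dtype=np.float64)
        if self.cls not in CLASSES:
            raise SchemaError(
                f"trichome {self.id!r}: class must be one of {CLASSES}, got {self.cls}"
            )

    def xy_um(self, cal: Calibration) -> np.ndarray:
        return self.xy_px * cal.um_per_px


@dataclass
class LeafFrame:
    """Leaf coordinate frame: origin and longitudinal-axis tip, in µm.

    The unit vector origin→tip defines the y direction; its length defines
    the unit of both axes, so the tip maps to (0, 1).
    """

    origin_um: np.ndarray
    tip_um: np.ndarray

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=np.float64)
        self.tip_um = np.asarray(self.tip_um, dtype=np.float64)
        if np.allclose(self.origin_um, self.tip_um):
            raise FrameError("frame origin and axis tip coincide")

    @property
    def scale_um(self) -> float:
        return float(np.linalg.norm(self.tip_um - self.origin_um))

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        y_hat = (self.tip_um - self.origin_um) / self.scale_um
        x_hat = np.array([y_hat[1], -y_hat[0]])
        return x_hat, y_hat

    @classmethod
    def suggest_from_mask(cls, mask: LeafMask, origin_um, um_per_px: float = 1.0):
        """Centroid-based axis suggestion: y-axis from origin through the
        mask's center of mass, scaled to reach the farthest in-mask point."""
        yy, xx = np.nonzero(mask.mask)
        com = np.array([xx.mean(), yy.mean()]) * um_per_px
        origin_um = np.asarray(origin_um, dtype=np.float64)
        d = com - origin_um
        nd = np.linalg.norm(d)
        if nd == 0:
            raise FrameError("mask center of mass coincides with origin")
        y_hat = d / nd
        proj = (np.column_stack([xx, yy]) * um_per_px - origin_um) @ y_hat
        return cls(origin_um=origin_um, tip_um=origin_um + y_hat * proj.max())


def to_frame(point_um, frame: LeafFrame) -> np.ndarray:
    """Normalized leaf coordinates of a µm point (tip at (0, 1))."""
    p = np.asarray(point_um, dtype=np.float64)
    x_hat, y_hat = frame.axes()
    d = p - frame.origin_um
    return np.array([d @ x_hat, d @ y_hat]) / frame.scale_um


def select_leaf(trichomes) -> bool:
    """Accept a leaf iff it carries one to six mature (class 4) trichomes."""
    n_mature = sum(1 for t in trichomes if t.cls == 4)
    return 1 <= n_mature <= 6


@dataclass
class Leaf:
    """One annotated leaf with its reconstruction artifacts."""

    leaf_id: str
    genotype: str
    trichomes: list
    frame: LeafFrame
    cal: Calibration
    emap: ElasticMap | None = None
    mask: LeafMask | None = None
    _mesh: SurfaceMesh | None = field(default=None, repr=False)

    @property
    def mesh(self) -> SurfaceMesh | None:
        """Triangulated surface restricted to the leaf outline (if masked)."""
        if self._mesh is None and self.emap is not None:
            mesh = triangulate(self.emap)
            if self.mask is not None:
                mesh = mesh.restrict_to(self.leaf_polygon_um())
            self._mesh = mesh
        return self._mesh

    @mesh.setter
    def mesh(self, value) -> None:
        self._mesh = value

    def trichome_xy_um(self) -> np.ndarray:
        return np.array([t.xy_um(self.cal) for t in self.trichomes])

    def trichome_classes(self) -> np.ndarray:
        return np.array([t.cls for t in self.trichomes])

    def leaf_polygon_um(self) -> Polygon:
        if self.mask is None:
            raise InputError(f"leaf {self.leaf_id}: no mask available")
        return Polygon(self.mask.boundary * self.cal.um_per_px)


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def load_annotations(path, cal: Calibration | None = None):
    """Read one leaf's annotations (JSON or CSV).

    JSON schema: {"leaf_id", "genotype", "frame": {"origin_px": [x, y],
    "tip_px": [x, y]}, "trichomes": [{"id", "x_px", "y_px", "class"}, ...]}.

    CSV schema: columns leaf_id, genotype, trichome_id, x_px, y_px, class,
    origin_x_px, origin_y_px, tip_x_px, tip_y_px (frame columns constant
    across rows).

    Returns (trichomes, frame, genotype); the frame is converted to µm
    using ``cal`` (identity scale if omitted).
    """
    path = Path(path)
    um_per_px = cal.um_per_px if cal is not None else 1.0
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("leaf_id", "genotype", "frame", "trichomes"):
            if key not in doc:
                raise SchemaError(f"{path}: missing top-level key {key!r}")
        fr = doc["frame"]
        if "origin_px" not in fr or "tip_px" not in fr:
            raise SchemaError(f"{path}: frame must define origin_px and tip_px")
        trichomes = []
        for rec in doc["trichomes"]:
            try:
                trichomes.append(
                    Trichome(
                        id=str(rec["id"]),
                        xy_px=(float(rec["x_px"]), float(rec["y_px"])),
                        cls=int(rec["class"]),
                    )
                )
            except KeyError as e:
                raise SchemaError(f"{path}: trichome record {rec!r} missing {e}") from e
        frame = LeafFrame(
            origin_um=np.asarray(fr["origin_px"], dtype=np.float64) * um_per_px,
            tip_um=np.asarray(fr["tip_px"], dtype=np.float64) * um_per_px,
        )
        return trichomes, frame, str(doc["genotype"])
    # CSV
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise SchemaError(f"{path}: no annotation rows")
    required = {
        "leaf_id", "genotype", "trichome_id", "x_px", "y_px", "class",
        "origin_x_px", "origin_y_px", "tip_x_px", "tip_y_px",
    }
    missing = required - set(rows[0])
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    trichomes = [
        Trichome(
            id=str(r["trichome_id"]),
            xy_px=(float(r["x_px"]), float(r["y_px"])),
            cls=int(r["class"]),
        )
        for r in rows
    ]
    r0 = rows[0]
    frame = LeafFrame(
        origin_um=np.array([float(r0["origin_x_px"]), float(r0["origin_y_px"])]) * um_per_px,
        tip_um=np.array([float(r0["tip_x_px"]), float(r0["tip_y_px"])]) * um_per_px,
    )
    return trichomes, frame, str(r0["genotype"])


def write_annotations(path, leaf_id, genotype, trichomes, frame_px) -> None:
    """Write one leaf's annotations as JSON (pixel coordinates)."""
    origin_px, tip_px = frame_px
    doc = {
        "leaf_id": str(leaf_id),
        "genotype": str(genotype),
        "frame": {
            "origin_px": [float(origin_px[0]), float(origin_px[1])],
            "tip_px": [float(tip_px[0]), float(tip_px[1])],
        },
        "trichomes": [
            {
                "id": t.id,
                "x_px": float(t.xy_px[0]),
                "y_px": float(t.xy_px[1]),
                "class": int(t.cls),
            }
            for t in trichomes
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# meta leaf
# ---------------------------------------------------------------------------


@dataclass
class MetaLeaf:
    """Pooled frame-normalized trichome records across leaves."""

    records: pd.DataFrame  # columns: leaf_id, genotype, cls, x, y

    def __len__(self) -> int:
        return len(self.records)


def build_metaleaf(leaves) -> MetaLeaf:
    """Pool the frame-normalized trichome positions of several leaves."""
    if not leaves:
        raise InputError("no leaves to pool")
    rejected = [lf.leaf_id for lf in leaves if not select_leaf(lf.trichomes)]
    if rejected:
        raise InputError(
            f"leaves {rejected} fail selection (need 1-6 mature trichomes)"
        )
    rows = []
    for lf in leaves:
        for t in lf.trichomes:
            x, y = to_frame(t.xy_um(lf.cal), lf.frame)
            rows.append((lf.leaf_id, lf.genotype, t.cls, x, y))
    return MetaLeaf(
        records=pd.DataFrame(rows, columns=["leaf_id", "genotype", "cls", "x", "y"])
    )


def longitudinal_profile(meta: MetaLeaf, n_bins: int = 10) -> pd.DataFrame:
    """Per-bin class proportions along the normalized longitudinal axis.

    Bins span [0, max(y)]; in occupied bins the four proportions sum to 1,
    empty bins are flagged (proportions NaN).
    """
    if n_bins < 1:
        raise InputError(f"n_bins must be >= 1, got {n_bins}")
    y = meta.records["y"].to_numpy()
    cls = meta.records["cls"].to_numpy()
    edges = np.linspace(0.0, max(y.max(), 1e-12), n_bins + 1)
    which = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        n = int(sel.sum())
        center = 0.5 * (edges[b] + edges[b + 1])
        if n == 0:
            rows.append([center, n, False] + [np.nan] * 4)
        else:
            props = [float((cls[sel] == c).sum()) / n for c in CLASSES]
            rows.append([center, n, True] + props)
    return pd.DataFrame(
        rows, columns=["y", "n", "occupied", "p1", "p2", "p3", "p4"]
    )


def metaleaf_histogram(meta: MetaLeaf, grid: tuple[int, int] = (10, 10)):
    """Per-cell, per-class counts over a (nx, ny) grid in meta-leaf space.

    Returns (counts, x_edges, y_edges) with counts of shape (4, ny, nx);
    the total count equals the number of records.
    """
    nx, ny = grid
    x = meta.records["x"].to_numpy()
    y = meta.records["y"].to_numpy()
    x_edges = np.linspace(x.min(), x.max() + 1e-12, nx + 1)
    y_edges = np.linspace(y.min(), y.max() + 1e-12, ny + 1)
    counts = np.zeros((4, ny, nx))
    for ci, c in enumerate(CLASSES):
        sel = meta.records["cls"].to_numpy() == c
        h, _, _ = np.histogram2d(y[sel], x[sel], bins=[y_edges, x_edges])
        counts[ci] = h
    return counts, x_edges, y_edges


def base_distance(trichomes, frame: LeafFrame, cal: Calibration) -> pd.DataFrame:
    """Signed distance of each trichome from the leaf base line.

    The base line is the frame's x-axis; the distance is the normalized y
    coordinate (tip = 1).  Raw µm values are also reported.
    """
    rows = []
    for t in trichomes:
        _, y = to_frame(t.xy_um(cal), frame)
        rows.append((t.id, t.cls, y, y * frame.scale_um))
    return pd.DataFrame(rows, columns=["trichome_id", "cls", "y_norm", "y_um"])


def density(trichomes, mesh: SurfaceMesh) -> dict:
    """Trichomes per µm² of 3D leaf area, per class and total."""
    a = geometry.area3d(mesh)
    if a <= 0:
        raise InputError("zero leaf area")
    out = {c: sum(1 for t in trichomes if t.cls == c) / a for c in CLASSES}
    out["total"] = len(list(trichomes)) / a
    return out


def class_abundance(leaves) -> pd.DataFrame:
    """Relative abundance (%) of trichome classes per genotype: mean of
    per-leaf proportions, with the across-leaf standard deviation."""
    rows = []
    for lf in leaves:
        cls = lf.trichome_classes()
        n = len(cls)
        for c in CLASSES:
            rows.append((lf.genotype, lf.leaf_id, c, 100.0 * (cls == c).sum() / n))
    df = pd.DataFrame(rows, columns=["genotype", "leaf_id", "cls", "pct"])
    out = (
        df.groupby(["genotype", "cls"])["pct"]
        .agg(mean_pct="mean", sd_pct=lambda v: float(np.std(v, ddof=0)), n_leaves="count")
        .reset_index()
    )
    return out


def leaf_morphometrics(
    mask: LeafMask, frame: LeafFrame, mesh: SurfaceMesh, um_per_px: float = 1.0
) -> dict:
    """3D leaf area, leaf length and leaf index.

    Length is the extent of the mask along the frame's longitudinal axis
    measured from the base point; leaf index is minor/major axis of the
    mask's best-fit ellipse (second image moments), always in (0, 1].
    """
    from skimage import measure

    if mask.area_px == 0:
        raise InputError("empty mask")
    props = measure.regionprops(mask.mask.astype(np.uint8))[0]
    if props.axis_major_length == 0:
        raise InputError("degenerate mask: zero major axis")
    leaf_index = props.axis_minor_length / props.axis_major_length
    yy, xx = np.nonzero(mask.mask)
    _, y_hat = frame.axes()
    proj = (np.column_stack([xx, yy]) * um_per_px - frame.origin_um) @ y_hat
    return {
        "area3d_um2": geometry.area3d(mesh),
        "length_um": float(proj.max()),
        "leaf_index": float(leaf_index),
    }


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum and genotype comparison
# ---------------------------------------------------------------------------


def wilcoxon_ranksum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test.

    Exact null distribution when n_a + n_b <= 20 and there are no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.  Returns (U statistic of sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(pooled) <= 20:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(min(res.pvalue, 1.0))
    ranks = sps.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    na, nb = len(a), len(b)
    u = ra - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(var)
    return float(u), float(min(1.0, 2.0 * sps.norm.sf(z)))


def genotype_statistics(leaves) -> dict:
    """Per-genotype-group samples of every compared statistic.

    Returns a dict mapping (statistic, class-or-None) to a 1D sample:
    per-leaf values for densities and morphometrics, pooled per-trichome
    values for Voronoi areas and geodesic nearest-neighbor distances.
    """
    out: dict = {}

    def add(key, value):
        out.setdefault(key, []).append(value)

    for lf in leaves:
        mesh = lf.mesh
        cls = lf.trichome_classes()
        if mesh is not None:
            dens = density(lf.trichomes, mesh)
            for c in CLASSES:
                add(("density", c), dens[c])
        if lf.mask is not None:
            morpho = leaf_morphometrics(lf.mask, lf.frame, mesh, lf.cal.um_per_px)
            add(("leaf_area", None), morpho["area3d_um2"])
            add(("leaf_length", None), morpho["length_um"])
            add(("leaf_index", None), morpho["leaf_index"])
        xy = lf.trichome_xy_um()
        if lf.mask is not None and len(xy) >= 3:
            v2 = geometry.voronoi_2d(xy, lf.leaf_polygon_um())
            for i in range(len(xy)):
                if v2.finite[i]:
                    add(("voronoi2d", int(cls[i])), v2.areas[i])
        if mesh is not None and len(xy) >= 2:
            pts = [mesh.locate_xy(p) for p in xy]
            v3 = geometry.voronoi_3d(pts, mesh)
            for i in range(len(xy)):
                if v3.finite[i]:
                    add(("voronoi3d", int(cls[i])), v3.areas[i])
            nn = geometry.geodesic_nn(mesh, pts)
            for i in range(len(xy)):
                add(("geodesic_nn", int(cls[i])), nn[i])
    return {k: np.asarray(v) for k, v in out.items()}


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=np.float64)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


def compare_genotypes(group_a, group_b, alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon comparison of spatial statistics between two genotypes.

    ``group_a`` / ``group_b`` are lists of :class:`Leaf` (statistics are
    computed here) or precomputed dicts from :func:`genotype_statistics`.
    Mature-trichome (class 4) tests are suppressed: leaves are selected by
    their mature count, which makes that comparison meaningless.  Raw
    p-values carry the headline significance flags; a Benjamini–Hochberg
    column is reported alongside.
    """
    if isinstance(group_a, dict):
        stats_a = group_a
    else:
        if not group_a:
            raise InputError("group_a is empty")
        stats_a = genotype_statistics(group_a)
    if isinstance(group_b, dict):
        stats_b = group_b
    else:
        if not group_b:
            raise InputError("group_b is empty")
        stats_b = genotype_statistics(group_b)
    rows = []
    keys = sorted(set(stats_a) | set(stats_b), key=lambda k: (k[0], k[1] or 0))
    for key in keys:
        stat, cls = key
        sa = stats_a.get(key, np.array([]))
        sb = stats_b.get(key, np.array([]))
        if cls == 4:
            rows.append(
                (stat, cls, len(sa), len(sb), np.nan, np.nan, False,
                 "not tested: leaves are selected by mature-trichome count")
            )
            continue
        if len(sa) == 0 or len(sb) == 0:
            rows.append((stat, cls, len(sa), len(sb), np.nan, np.nan, False,
                         "sample missing in one group"))
            continue
        u, p = wilcoxon_ranksum(sa, sb)
        rows.append((stat, cls, len(sa), len(sb), u, p, True, ""))
    df = pd.DataFrame(
        rows,
        columns=["statistic", "cls", "n_a", "n_b", "U", "p", "tested", "note"],
    )
    tested = df["tested"] & df["p"].notna()
    df["p_bh"] = np.nan
    if tested.any():
        df.loc[tested, "p_bh"] = _bh_adjust(df.loc[tested, "p"].to_numpy())
    df["significant"] = tested & (df["p"] < alpha)
    return df
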