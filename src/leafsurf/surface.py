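"""Elastic-map surface fitting and triangulation.

The best-focus height map is a noisy point cloud S of (x, y, z) tuples, not
a surface: z-positioning jitter and focus-measure failures scatter points
off the true lamina.  An elastic map — a rectangular grid of 3D nodes with
a spring-like energy — is fitted to S as a principal-manifold approximator
and serves as the smooth 2D-manifold model of the leaf surface.

Three energies are minimized jointly:

* data energy      U_Y = (1/|S|) sum_j sum_{s in K_j} w_s ||s - y_j||^2,
  where K_j is the set of points hosted by (closest to) node y_j;
* stretching       U_E = lambda * sum_{(i,j) in E} ||y_i - y_j||^2
  over the 4-neighbor grid edges E;
* bending          U_R = mu * sum_{(i,j,k) in R} ||y_i - 2 y_j + y_k||^2
  over the ribs R (all triples of three consecutive nodes along grid rows
  and columns; the second difference measures local curvature).

Fitting alternates an E-step (re-assign each point to its nearest node)
with an M-step (exact minimization of the total energy in the node
positions, a sparse linear solve per coordinate); the total energy is
non-increasing across iterations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .errors import DomainError, FitError, InputError, MeshError
from .focus import HeightMap
from .segmentation import LeafMask
from .stackio import Calibration

__all__ = [
    "FocusPointCloud",
    "ElasticMap",
    "SurfaceMesh",
    "SurfacePoint",
    "build_cloud",
    "elastic_energy",
    "fit_elastic_map",
    "evaluate_surface",
    "triangulate",
]


@dataclass
class FocusPointCloud:
    """(x, y, z) points in µm, one per retained in-mask pixel."""

    points: np.ndarray  # (N, 3)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InputError(f"points must be (N, 3), got {self.points.shape}")
        if self.points.shape[0] == 0:
            raise InputError("point cloud is empty")
        if not np.all(np.isfinite(self.points)):
            raise InputError("point cloud contains non-finite coordinates")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (len(self.points),) or np.any(self.weights <= 0):
                raise InputError("weights must be positive, one per point")

    def __len__(self) -> int:
        return len(self.points)


def build_cloud(
    hm: HeightMap,
    mask: LeafMask | np.ndarray,
    cal: Calibration,
    subsample: int = 1,
) -> FocusPointCloud:
    """Convert an in-mask height map to a µm point cloud.

    ``subsample`` keeps every subsample-th pixel along each axis (stride),
    which is usually plenty for a 30x30-node map and much faster.
    """
    m = mask.mask if isinstance(mask, LeafMask) else np.asarray(mask, dtype=bool)
    if m.shape != hm.shape:
        raise InputError(f"mask shape {m.shape} != height map shape {hm.shape}")
    if subsample < 1:
        raise InputError(f"subsample must be >= 1, got {subsample}")
    keep = np.zeros_like(m)
    keep[::subsample, ::subsample] = True
    sel = m & keep
    if not sel.any():
        raise InputError("no in-mask pixels retained")
    yy, xx = np.nonzero(sel)
    pts = np.column_stack(
        [xx * cal.um_per_px, yy * cal.um_per_px, hm.z_um[yy, xx]]
    )
    return FocusPointCloud(points=pts)


@dataclass
class ElasticMap:
    """Grid of 3D nodes with stretching (lambda) and bending (mu) stiffness.

    ``nodes`` has shape (n, m, 3): index i runs along y, j along x, and the
    last axis holds (x, y, z) in µm.
    """

    nodes: np.ndarray
    lam: float = 0.001
    mu: float = 0.01
    #: (x, y) rectangle the surface answers queries on; the fit sets this to
    #: the cloud bounding box (the node grid contracts slightly inside it)
    domain: tuple | None = None
    energy_trace_: list = field(default_factory=list, repr=False)
    n_iter_: int = 0

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=np.float64)
        if self.nodes.ndim != 3 or self.nodes.shape[2] != 3:
            raise InputError(f"nodes must be (n, m, 3), got {self.nodes.shape}")
        if self.lam < 0 or self.mu < 0:
            raise InputError("lambda and mu must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.nodes.shape[:2]

    def node_index(self, i: int, j: int) -> int:
        return i * self.nodes.shape[1] + j

    def edges(self) -> np.ndarray:
        """4-neighbor grid adjacencies as (n_edges, 2) flat node indices."""
        n, m = self.grid_shape
        idx = np.arange(n * m).reshape(n, m)
        horiz = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
        vert = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
        return np.vstack([horiz, vert])

    def ribs(self) -> np.ndarray:
        """Triples of three consecutive nodes along rows and columns."""
        n, m = self.grid_shape
        idx = np.arange(n * m).reshape(n, m)
        along_x = np.column_stack(
            [idx[:, :-2].ravel(), idx[:, 1:-1].ravel(), idx[:, 2:].ravel()]
        )
        along_y = np.column_stack(
            [idx[:-2, :].ravel(), idx[1:-1, :].ravel(), idx[2:, :].ravel()]
        )
        return np.vstack([along_x, along_y])

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "lambda": self.lam,
            "mu": self.mu,
            "domain": list(self.domain) if self.domain is not None else None,
            "nodes": self.nodes.reshape(-1, 3).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ElasticMap":
        with open(path) as fh:
            payload = json.load(fh)
        n, m = payload["grid_shape"]
        nodes = np.asarray(payload["nodes"], dtype=np.float64).reshape(n, m, 3)
        domain = payload.get("domain")
        return cls(
            nodes=nodes,
            lam=payload["lambda"],
            mu=payload["mu"],
            domain=tuple(domain) if domain else None,
        )


def assign_points(emap: ElasticMap, cloud: FocusPointCloud) -> np.ndarray:
    """Host-node assignment: each point goes to its nearest node (3D)."""
    tree = cKDTree(emap.nodes.reshape(-1, 3))
    _, host = tree.query(cloud.points)
    return host


def elastic_energy(
    emap: ElasticMap,
    cloud: FocusPointCloud | None,
    assignment: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """(U_Y, U_E, U_R, total) for the map, cloud and host assignment.

    With ``cloud=None`` only the elastic terms are evaluated (U_Y = 0).
    If ``assignment`` is omitted it is recomputed as nearest-node.
    """
    flat = emap.nodes.reshape(-1, 3)
    if cloud is None:
        u_y = 0.0
    else:
        if assignment is None:
            assignment = assign_points(emap, cloud)
        w = cloud.weights if cloud.weights is not None else np.ones(len(cloud))
        d2 = np.sum((cloud.points - flat[assignment]) ** 2, axis=1)
        u_y = float(np.sum(w * d2) / len(cloud))
    e = emap.edges()
    u_e = float(emap.lam * np.sum((flat[e[:, 0]] - flat[e[:, 1]]) ** 2))
    r = emap.ribs()
    second = flat[r[:, 0]] - 2.0 * flat[r[:, 1]] + flat[r[:, 2]]
    u_r = float(emap.mu * np.sum(second**2))
    return u_y, u_e, u_r, u_y + u_e + u_r


def _elastic_operator(n: int, m: int, lam: float, mu: float) -> sparse.csr_matrix:
    """Sparse quadratic-form matrix of lambda*U_E + mu*U_R (per coordinate)."""
    emap = ElasticMap(nodes=np.zeros((n, m, 3)), lam=lam, mu=mu)
    rows, cols, vals = [], [], []
    if lam > 0:
        for a, b in emap.edges():
            rows += [a, b, a, b]
            cols += [a, b, b, a]
            vals += [lam, lam, -lam, -lam]
    if mu > 0:
        coef = np.array([1.0, -2.0, 1.0])
        for trip in emap.ribs():
            for ai, ci in enumerate(trip):
                for bi, cj in enumerate(trip):
                    rows.append(ci)
                    cols.append(cj)
                    vals.append(mu * coef[ai] * coef[bi])
    N = n * m
    return sparse.csr_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(N, N)
    )


def _init_grid(points: np.ndarray, n: int, m: int) -> np.ndarray:
    """Regular (x, y) grid over the cloud bounding box, z from a LSQ plane."""
    x0, y0 = points[:, 0].min(), points[:, 1].min()
    x1, y1 = points[:, 0].max(), points[:, 1].max()
    gx = np.linspace(x0, x1, m)
    gy = np.linspace(y0, y1, n)
    X, Y = np.meshgrid(gx, gy)
    A = np.column_stack([points[:, 0], points[:, 1], np.ones(len(points))])
    coef, *_ = np.linalg.lstsq(A, points[:, 2], rcond=None)
    Z = coef[0] * X + coef[1] * Y + coef[2]
    return np.stack([X, Y, Z], axis=-1)


def fit_elastic_map(
    cloud: FocusPointCloud,
    grid_shape: tuple[int, int] = (30, 30),
    lam: float = 0.001,
    mu: float = 0.01,
    max_iter: int = 100,
    tol: float = 1e-5,
    anchor_boundary: bool = True,
) -> ElasticMap:
    """Fit an elastic map to a point cloud by alternating minimization.

    Coordinates are internally rescaled so the cloud's bounding-box
    diagonal has unit length; lambda and mu therefore act on
    dimensionless, leaf-size-independent coordinates, and one set of
    defaults works across magnifications.  Node positions are returned in
    the original µm coordinates.  ``energy_trace_`` records the total
    energy (normalized coordinates) after each iteration.

    With ``anchor_boundary`` (default) the (x, y) positions of the
    grid's boundary ring stay pinned to the data bounding box, so the
    fitted surface always spans the full leaf footprint; the zero
    rest length of the stretching springs would otherwise contract the
    grid inside the data and leave edge trichomes off the surface.  Node
    z and interior (x, y) are free in either case.
    """
    n, m = grid_shape
    if n < 2 or m < 2:
        raise InputError(f"grid must be at least 2x2, got {grid_shape}")
    pts = cloud.points
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    scale = float(np.linalg.norm(hi - lo))
    if scale == 0:
        raise FitError("degenerate cloud: all points coincide")
    spts = (pts - lo) / scale
    w = cloud.weights if cloud.weights is not None else np.ones(len(cloud))
    N = n * m

    nodes = _init_grid(spts, n, m)
    op = _elastic_operator(n, m, lam, mu)
    emap = ElasticMap(nodes=nodes, lam=lam, mu=mu)
    scloud = FocusPointCloud(points=spts, weights=cloud.weights)

    boundary = np.zeros((n, m), dtype=bool)
    boundary[0, :] = boundary[-1, :] = boundary[:, 0] = boundary[:, -1] = True
    boundary = boundary.ravel()
    free = ~boundary
    anchor_xy = nodes.reshape(N, 3)[:, :2].copy()  # initial regular grid

    trace: list[float] = []
    prev = np.inf
    host = assign_points(emap, scloud)
    it = 0
    for it in range(1, max_iter + 1):
        wsum = np.bincount(host, weights=w, minlength=N)
        if lam == 0 and mu == 0 and np.any(wsum == 0):
            empty = np.nonzero(wsum == 0)[0].tolist()
            raise FitError(
                f"singular system: nodes {empty} host no points and "
                "lambda = mu = 0 leaves them unconstrained"
            )
        A = (op + sparse.diags(wsum / len(scloud))).tocsr()
        rhs = np.zeros((N, 3))
        np.add.at(rhs, host, w[:, None] * spts)
        rhs /= len(scloud)
        sol = np.empty((N, 3))
        try:
            if anchor_boundary:
                # x, y: Dirichlet on the boundary ring; z: unconstrained
                sol[boundary, :2] = anchor_xy[boundary]
                if free.any():
                    A_ff = A[free][:, free].tocsc()
                    A_fb = A[free][:, boundary]
                    lu_f = splu(A_ff)
                    for c in range(2):
                        b_eff = rhs[free, c] - A_fb @ anchor_xy[boundary, c]
                        sol[free, c] = lu_f.solve(b_eff)
                sol[:, 2] = splu(A.tocsc()).solve(rhs[:, 2])
            else:
                lu = splu(A.tocsc())
                for c in range(3):
                    sol[:, c] = lu.solve(rhs[:, c])
        except RuntimeError as e:
            raise FitError(f"singular elastic system: {e}") from e
        emap.nodes = sol.reshape(n, m, 3)
        host = assign_points(emap, scloud)
        total = elastic_energy(emap, scloud, host)[3]
        trace.append(total)
        if prev < np.inf and prev - total <= tol * max(prev, 1e-300):
            break
        prev = total

    emap.nodes = emap.nodes * scale + lo
    emap.domain = (
        float(pts[:, 0].min()), float(pts[:, 0].max()),
        float(pts[:, 1].min()), float(pts[:, 1].max()),
    )
    emap.energy_trace_ = trace
    emap.n_iter_ = it
    return emap


# ---------------------------------------------------------------------------
# surface evaluation (warped bilinear interpolation on the node grid)
# ---------------------------------------------------------------------------


def _inverse_bilinear(q, p00, p10, p01, p11, n_iter: int = 12):
    """Local (u, v) of query q in the quad via Newton; may fall outside [0,1]."""
    u, v = 0.5, 0.5
    for _ in range(n_iter):
        one_u, one_v = 1.0 - u, 1.0 - v
        P = one_u * one_v * p00 + u * one_v * p10 + one_u * v * p01 + u * v * p11
        r = P - q
        du = one_v * (p10 - p00) + v * (p11 - p01)
        dv = one_u * (p01 - p00) + u * (p11 - p10)
        det = du[0] * dv[1] - du[1] * dv[0]
        if det == 0:
            break
        su = (r[0] * dv[1] - r[1] * dv[0]) / det
        sv = (du[0] * r[1] - du[1] * r[0]) / det
        u -= su
        v -= sv
        if abs(su) < 1e-14 and abs(sv) < 1e-14:
            break
    return u, v


def evaluate_surface(emap: ElasticMap, xy: np.ndarray) -> np.ndarray | float:
    """Height z = f(x, y) of the map surface at query points.

    Bilinear interpolation of node z within the containing grid cell.  The
    node grid may be mildly warped by the fit; cells are located by
    candidate-cell search plus inverse-bilinear Newton iteration.  Queries
    up to 2% of the domain extent outside the surface (annotations are
    marked on the full image, the surface covers the segmented leaf) are
    clamped to the domain edge; queries farther out raise
    :class:`DomainError`.
    """
    xy = np.asarray(xy, dtype=np.float64)
    single = xy.ndim == 1
    q = xy[None, :].copy() if single else xy.copy()
    n, m = emap.grid_shape
    P = emap.nodes[..., :2]
    Z = emap.nodes[..., 2]
    bb_lo = P.reshape(-1, 2).min(axis=0)
    bb_hi = P.reshape(-1, 2).max(axis=0)
    if emap.domain is not None:
        x0, x1, y0, y1 = emap.domain
        bb_lo = np.minimum(bb_lo, [x0, y0])
        bb_hi = np.maximum(bb_hi, [x1, y1])
    extent = float(np.linalg.norm(bb_hi - bb_lo))
    tol = 1e-9 * max(extent, 1.0)
    clamp_margin = 0.02 * extent
    # per-cell bounding boxes
    cx0 = np.minimum.reduce([P[:-1, :-1, 0], P[:-1, 1:, 0], P[1:, :-1, 0], P[1:, 1:, 0]])
    cx1 = np.maximum.reduce([P[:-1, :-1, 0], P[:-1, 1:, 0], P[1:, :-1, 0], P[1:, 1:, 0]])
    cy0 = np.minimum.reduce([P[:-1, :-1, 1], P[:-1, 1:, 1], P[1:, :-1, 1], P[1:, 1:, 1]])
    cy1 = np.maximum.reduce([P[:-1, :-1, 1], P[:-1, 1:, 1], P[1:, :-1, 1], P[1:, 1:, 1]])
    out = np.empty(len(q))
    eps = 1e-9
    for k, pt in enumerate(q):
        if np.any(pt < bb_lo - clamp_margin) or np.any(pt > bb_hi + clamp_margin):
            raise DomainError(f"query {tuple(pt)} outside the surface domain")
        pt = np.clip(pt, bb_lo, bb_hi)
        cand = np.argwhere(
            (cx0 - tol <= pt[0]) & (pt[0] <= cx1 + tol)
            & (cy0 - tol <= pt[1]) & (pt[1] <= cy1 + tol)
        )
        best = None  # (violation, z)
        for i, j in cand:
            p00, p10 = P[i, j], P[i, j + 1]
            p01, p11 = P[i + 1, j], P[i + 1, j + 1]
            u, v = _inverse_bilinear(pt, p00, p10, p01, p11)
            viol = max(0.0, -u, u - 1.0, -v, v - 1.0)
            uc, vc = min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0)
            z = (
                (1 - uc) * (1 - vc) * Z[i, j]
                + uc * (1 - vc) * Z[i, j + 1]
                + (1 - uc) * vc * Z[i + 1, j]
                + uc * vc * Z[i + 1, j + 1]
            )
            if viol <= eps:
                best = (0.0, z)
                break
            if best is None or viol < best[0]:
                best = (viol, z)
        if best is None:
            # inside bbox but no cell bbox matched (strong warp); use nearest cell
            centers = (P[:-1, :-1] + P[:-1, 1:] + P[1:, :-1] + P[1:, 1:]) / 4.0
            d2 = np.sum((centers - pt) ** 2, axis=-1)
            i, j = np.unravel_index(np.argmin(d2), d2.shape)
            u, v = _inverse_bilinear(pt, P[i, j], P[i, j + 1], P[i + 1, j], P[i + 1, j + 1])
            uc, vc = min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0)
            best = (
                0.0,
                (1 - uc) * (1 - vc) * Z[i, j]
                + uc * (1 - vc) * Z[i, j + 1]
                + (1 - uc) * vc * Z[i + 1, j]
                + uc * vc * Z[i + 1, j + 1],
            )
        out[k] = best[1]
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# triangulated mesh
# ---------------------------------------------------------------------------


@dataclass
class SurfacePoint:
    """A point on a mesh: triangle index + barycentric coordinates."""

    tri: int
    bary: np.ndarray

    def position(self, mesh: "SurfaceMesh") -> np.ndarray:
        v = mesh.vertices[mesh.triangles[self.tri]]
        return np.asarray(self.bary, dtype=np.float64) @ v


class SurfaceMesh:
    """Triangulated surface: vertices (µm), triangles, per-vertex (x, y) uv."""

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray, uv: np.ndarray | None = None):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.triangles = np.asarray(triangles, dtype=np.int64)
        self.uv = self.vertices[:, :2].copy() if uv is None else np.asarray(uv, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError(f"triangles must be (T, 3), got {self.triangles.shape}")
        self._v2t = None
        self._tree = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas_3d(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def triangle_areas_2d(self) -> np.ndarray:
        """Areas of the triangles projected onto the (x, y) plane."""
        v = self.vertices[self.triangles][:, :, :2]
        cross = (v[:, 1, 0] - v[:, 0, 0]) * (v[:, 2, 1] - v[:, 0, 1]) - (
            v[:, 1, 1] - v[:, 0, 1]
        ) * (v[:, 2, 0] - v[:, 0, 0])
        return 0.5 * np.abs(cross)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one triangle, as (n, 2) vertex indices."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_triangles(self) -> np.ndarray:
        """Boolean flag per triangle: has an edge on the mesh boundary."""
        bset = {tuple(x) for x in self.boundary_edges()}
        t = self.triangles
        flags = np.zeros(len(t), dtype=bool)
        for k in range(len(t)):
            a, b, c = t[k]
            if (
                tuple(sorted((a, b))) in bset
                or tuple(sorted((b, c))) in bset
                or tuple(sorted((c, a))) in bset
            ):
                flags[k] = True
        return flags

    def vertex_triangles(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR adjacency: (indptr, tri_indices) per vertex."""
        if self._v2t is None:
            t = self.triangles
            counts = np.bincount(t.ravel(), minlength=self.n_vertices)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            data = np.empty(indptr[-1], dtype=np.int64)
            cursor = indptr[:-1].copy()
            for k in range(len(t)):
                for v in t[k]:
                    data[cursor[v]] = k
                    cursor[v] += 1
            self._v2t = (indptr.astype(np.int64), data)
        return self._v2t

    # -- point location ------------------------------------------------

    def _bary_2d(self, tri: int, xy: np.ndarray) -> np.ndarray:
        a, b, c = self.uv[self.triangles[tri]]
        T = np.column_stack([b - a, c - a])
        det = T[0, 0] * T[1, 1] - T[0, 1] * T[1, 0]
        if det == 0:
            return np.array([np.inf, np.inf, np.inf])
        r = xy - a
        l1 = (r[0] * T[1, 1] - r[1] * T[0, 1]) / det
        l2 = (T[0, 0] * r[1] - T[1, 0] * r[0]) / det
        return np.array([1.0 - l1 - l2, l1, l2])

    def locate_xy(self, xy: np.ndarray) -> SurfacePoint:
        """Surface point over the given (x, y) via the uv parameterization."""
        xy = np.asarray(xy, dtype=np.float64)
        if self._tree is None:
            self._tree = cKDTree(self.uv)
        indptr, tris = self.vertex_triangles()
        k = 8
        best = None
        while True:
            _, near = self._tree.query(xy, k=min(k, self.n_vertices))
            cand = set()
            for v in np.atleast_1d(near):
                cand.update(tris[indptr[v] : indptr[v + 1]].tolist())
            for t in cand:
                bary = self._bary_2d(t, xy)
                viol = max(0.0, -bary.min())
                if viol <= 1e-9:
                    return SurfacePoint(tri=t, bary=np.clip(bary, 0, 1))
                if best is None or viol < best[0]:
                    best = (viol, t, bary)
            if k >= self.n_vertices or (best is not None and best[0] < 1e-6):
                break
            k *= 4
        viol, t, bary = best
        bary = np.clip(bary, 0.0, None)
        return SurfacePoint(tri=t, bary=bary / bary.sum())

    def locate_3d(self, p: np.ndarray) -> SurfacePoint:
        """Nearest surface point to a 3D position (searched via vertices)."""
        p = np.asarray(p, dtype=np.float64)
        tree = cKDTree(self.vertices)
        _, v = tree.query(p)
        indptr, tris = self.vertex_triangles()
        best = None
        for t in tris[indptr[v] : indptr[v + 1]]:
            a, b, c = self.vertices[self.triangles[t]]
            # project p onto the triangle plane and solve barycentric
            n_vec = np.cross(b - a, c - a)
            nn = n_vec / (np.linalg.norm(n_vec) + 1e-300)
            proj = p - np.dot(p - a, nn) * nn
            M = np.column_stack([b - a, c - a])
            sol, *_ = np.linalg.lstsq(M, proj - a, rcond=None)
            bary = np.array([1.0 - sol.sum(), sol[0], sol[1]])
            bary = np.clip(bary, 0.0, None)
            bary = bary / bary.sum()
            pos = bary @ np.vstack([a, b, c])
            d = np.linalg.norm(pos - p)
            if best is None or d < best[0]:
                best = (d, t, bary)
        _, t, bary = best
        return SurfacePoint(tri=int(t), bary=bary)

    def as_surface_point(self, point) -> SurfacePoint:
        """Accept a SurfacePoint, a vertex index, a 2D or a 3D coordinate."""
        if isinstance(point, SurfacePoint):
            return point
        if np.isscalar(point) or (isinstance(point, np.integer)):
            indptr, tris = self.vertex_triangles()
            t = int(tris[indptr[int(point)]])
            bary = (self.triangles[t] == int(point)).astype(np.float64)
            return SurfacePoint(tri=t, bary=bary)
        point = np.asarray(point, dtype=np.float64)
        if point.shape == (2,):
            return self.locate_xy(point)
        if point.shape == (3,):
            return self.locate_3d(point)
        raise InputError(f"cannot interpret {point!r} as a surface point")

    def submesh(self, keep: np.ndarray) -> "SurfaceMesh":
        """New mesh with only the flagged triangles (vertices reindexed)."""
        keep = np.asarray(keep, dtype=bool)
        tris = self.triangles[keep]
        used = np.unique(tris)
        remap = -np.ones(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return SurfaceMesh(self.vertices[used], remap[tris], uv=self.uv[used])

    def restrict_to(self, region) -> "SurfaceMesh":
        """Submesh of triangles whose uv centroid lies inside a polygon."""
        import shapely

        cent = self.uv[self.triangles].mean(axis=1)
        inside = shapely.covers(region, shapely.points(cent[:, 0], cent[:, 1]))
        if not inside.any():
            raise MeshError("no triangles inside the region")
        return self.submesh(inside)

    # -- export --------------------------------------------------------

    def save_obj(self, path) -> None:
        with open(path, "w") as fh:
            for v in self.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in self.triangles:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")

    def save_ply(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {self.n_vertices}\n"
                "property float x\nproperty float y\nproperty float z\n"
                f"element face {self.n_triangles}\n"
                "property list uchar int vertex_indices\nend_header\n"
            )
            for v in self.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in self.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")

    @classmethod
    def from_grid(
        cls,
        X: np.ndarray,
        Y: np.ndarray,
        Z: np.ndarray,
        mask: np.ndarray | None = None,
        crosshatch: bool = False,
    ) -> "SurfaceMesh":
        """Mesh a height field sampled on a (possibly masked) regular grid.

        Each retained quad is split along the lower-left -> upper-right
        diagonal, or — with ``crosshatch=True`` — into four triangles
        around an added cell-center vertex, which roughly halves the
        direction-dependent error of geodesic propagation.  With a mask,
        only cells whose four corners are all inside are kept.
        """
        n, m = X.shape
        keep = np.ones((n, m), dtype=bool) if mask is None else np.asarray(mask, bool)
        vid = -np.ones((n, m), dtype=np.int64)
        used = np.zeros((n, m), dtype=bool)
        cells = keep[:-1, :-1] & keep[:-1, 1:] & keep[1:, :-1] & keep[1:, 1:]
        ci, cj = np.nonzero(cells)
        for i, j in zip(ci, cj):
            used[i : i + 2, j : j + 2] = True
        uy, ux = np.nonzero(used)
        vid[uy, ux] = np.arange(len(uy))
        verts = np.column_stack([X[uy, ux], Y[uy, ux], Z[uy, ux]])
        tris = []
        if crosshatch:
            centers = []
            next_id = len(verts)
            for i, j in zip(ci, cj):
                v00, v10 = vid[i, j], vid[i, j + 1]
                v01, v11 = vid[i + 1, j], vid[i + 1, j + 1]
                centers.append(verts[[v00, v10, v01, v11]].mean(axis=0))
                c = next_id
                next_id += 1
                tris += [[v00, v10, c], [v10, v11, c], [v11, v01, c], [v01, v00, c]]
            verts = np.vstack([verts, np.asarray(centers)])
        else:
            for i, j in zip(ci, cj):
                v00, v10 = vid[i, j], vid[i, j + 1]
                v01, v11 = vid[i + 1, j], vid[i + 1, j + 1]
                tris.append([v00, v10, v11])
                tris.append([v00, v11, v01])
        return cls(verts, np.asarray(tris, dtype=np.int64))


def triangulate(emap: ElasticMap) -> SurfaceMesh:
    """Split each grid quad into two triangles along the same diagonal.

    Every cell is cut lower-left -> upper-right, giving 2(n-1)(m-1)
    triangles with consistent orientation.  Degenerate (zero-area)
    triangles abort with a :class:`MeshError` naming the offending cells.
    """
    n, m = emap.grid_shape
    X, Y, Z = emap.nodes[..., 0], emap.nodes[..., 1], emap.nodes[..., 2]
    mesh = SurfaceMesh.from_grid(X, Y, Z)
    areas = mesh.triangle_areas_3d()
    if np.any(areas <= 0):
        bad = np.nonzero(areas <= 0)[0]
        cells = sorted({(int(t // 2) // (m - 1), int(t // 2) % (m - 1)) for t in bad})
        raise MeshError(f"degenerate triangles in grid cells {cells}")
    return mesh
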