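"""First-order fast-marching eikonal solver on triangle meshes.

Propagates a distance front from seeded vertices across the surface.  The
local update inside a triangle is the planar-wavefront solve of Kimmel &
Sethian: for a target vertex C with known neighbors A, B it finds the
arrival time consistent with a linear front crossing the triangle, subject
to the causality condition that the front direction points into the
triangle; otherwise it falls back to the edge (Dijkstra) update, which
keeps the solver monotone on obtuse configurations at some accuracy cost.

The kernel is JIT-compiled with numba; the hand-rolled binary heap uses
lazy deletion (stale entries are skipped on pop).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["fast_marching"]


@njit(cache=True)
def _heap_push(heap_d, heap_v, size, d, v):
    i = size
    heap_d[i] = d
    heap_v[i] = v
    while i > 0:
        parent = (i - 1) // 2
        if heap_d[parent] <= heap_d[i]:
            break
        heap_d[parent], heap_d[i] = heap_d[i], heap_d[parent]
        heap_v[parent], heap_v[i] = heap_v[i], heap_v[parent]
        i = parent
    return size + 1


@njit(cache=True)
def _heap_pop(heap_d, heap_v, size):
    d = heap_d[0]
    v = heap_v[0]
    size -= 1
    heap_d[0] = heap_d[size]
    heap_v[0] = heap_v[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        smallest = i
        if l < size and heap_d[l] < heap_d[smallest]:
            smallest = l
        if r < size and heap_d[r] < heap_d[smallest]:
            smallest = r
        if smallest == i:
            break
        heap_d[smallest], heap_d[i] = heap_d[i], heap_d[smallest]
        heap_v[smallest], heap_v[i] = heap_v[i], heap_v[smallest]
        i = smallest
    return d, v, size


@njit(cache=True)
def _tri_update(verts, ia, ib, ic, da, db):
    """Candidate distance at vertex ic from values da, db at ia, ib."""
    e1x = verts[ia, 0] - verts[ic, 0]
    e1y = verts[ia, 1] - verts[ic, 1]
    e1z = verts[ia, 2] - verts[ic, 2]
    e2x = verts[ib, 0] - verts[ic, 0]
    e2y = verts[ib, 1] - verts[ic, 1]
    e2z = verts[ib, 2] - verts[ic, 2]
    g11 = e1x * e1x + e1y * e1y + e1z * e1z
    g22 = e2x * e2x + e2y * e2y + e2z * e2z
    g12 = e1x * e2x + e1y * e2y + e1z * e2z
    la = math.sqrt(g11)
    lb = math.sqrt(g22)
    fallback = min(da + la, db + lb)
    det = g11 * g22 - g12 * g12
    if det <= 0.0:
        return fallback
    # quadratic for the planar-front arrival time p
    A = (g22 - 2.0 * g12 + g11) / det
    B = (g22 * da - g12 * (da + db) + g11 * db) / det
    C = (g22 * da * da - 2.0 * g12 * da * db + g11 * db * db) / det
    disc = B * B - A * (C - 1.0)
    if disc < 0.0 or A == 0.0:
        return fallback
    p = (B + math.sqrt(disc)) / A
    if p < da or p < db:
        return fallback
    # causality: gradient must point out of the triangle through C
    w1 = (g22 * (da - p) - g12 * (db - p)) / det
    w2 = (g11 * (db - p) - g12 * (da - p)) / det
    if w1 > 0.0 or w2 > 0.0:
        return fallback
    return p


@njit(cache=True)
def _fmm_kernel(verts, tris, v2t_indptr, v2t_data, seed_v, seed_d):
    n = verts.shape[0]
    INF = 1e300
    dist = np.full(n, INF)
    accepted = np.zeros(n, dtype=np.uint8)
    cap = 32 * n + 16 * seed_v.shape[0] + 64
    heap_d = np.empty(cap)
    heap_v = np.empty(cap, dtype=np.int64)
    size = 0
    for k in range(seed_v.shape[0]):
        v = seed_v[k]
        if seed_d[k] < dist[v]:
            dist[v] = seed_d[k]
    for k in range(seed_v.shape[0]):
        v = seed_v[k]
        size = _heap_push(heap_d, heap_v, size, dist[v], v)
    while size > 0:
        d, v, size = _heap_pop(heap_d, heap_v, size)
        if accepted[v] == 1 or d > dist[v]:
            continue
        accepted[v] = 1
        for ti in range(v2t_indptr[v], v2t_indptr[v + 1]):
            t = v2t_data[ti]
            for local in range(3):
                c = tris[t, local]
                if accepted[c] == 1:
                    continue
                a = tris[t, (local + 1) % 3]
                b = tris[t, (local + 2) % 3]
                da = dist[a]
                db = dist[b]
                if da >= INF and db >= INF:
                    continue
                if da >= INF or db >= INF:
                    # one-point (edge) update
                    if da >= INF:
                        a, da = b, db
                    ex = verts[a, 0] - verts[c, 0]
                    ey = verts[a, 1] - verts[c, 1]
                    ez = verts[a, 2] - verts[c, 2]
                    cand = da + math.sqrt(ex * ex + ey * ey + ez * ez)
                else:
                    cand = _tri_update(verts, a, b, c, da, db)
                if cand < dist[c]:
                    dist[c] = cand
                    if size < cap:
                        size = _heap_push(heap_d, heap_v, size, cand, c)
    return dist


@njit(cache=True)
def _relax_kernel(verts, tris, dist, seed_mask, max_passes, tol):
    """Gauss-Seidel sweeps of the local solver until convergence.

    Fast marching accepts vertices in causal order, so a vertex served only
    by an obtuse (fallback) update is frozen with an overestimate.
    Re-sweeping every triangle with converged neighbor values removes that
    ordering error; seeded vertices keep their exact values.
    """
    nt = tris.shape[0]
    for _ in range(max_passes):
        delta = 0.0
        for t in range(nt):
            for local in range(3):
                c = tris[t, local]
                if seed_mask[c] == 1:
                    continue
                a = tris[t, (local + 1) % 3]
                b = tris[t, (local + 2) % 3]
                da = dist[a]
                db = dist[b]
                if da >= 1e300 and db >= 1e300:
                    continue
                if da >= 1e300 or db >= 1e300:
                    if da >= 1e300:
                        a, da = b, db
                    ex = verts[a, 0] - verts[c, 0]
                    ey = verts[a, 1] - verts[c, 1]
                    ez = verts[a, 2] - verts[c, 2]
                    cand = da + math.sqrt(ex * ex + ey * ey + ez * ez)
                else:
                    cand = _tri_update(verts, a, b, c, da, db)
                if cand < dist[c]:
                    if dist[c] - cand > delta:
                        delta = dist[c] - cand
                    dist[c] = cand
        if delta < tol:
            break
    return dist


def fast_marching(
    verts, tris, v2t_indptr, v2t_data, seed_v, seed_d, relax_passes: int = 10
) -> np.ndarray:
    """Per-vertex distance field from seeded vertices (µm)."""
    verts = np.ascontiguousarray(verts, dtype=np.float64)
    tris = np.ascontiguousarray(tris, dtype=np.int64)
    seed_v = np.ascontiguousarray(seed_v, dtype=np.int64)
    dist = _fmm_kernel(
        verts,
        tris,
        np.ascontiguousarray(v2t_indptr, dtype=np.int64),
        np.ascontiguousarray(v2t_data, dtype=np.int64),
        seed_v,
        np.ascontiguousarray(seed_d, dtype=np.float64),
    )
    if relax_passes > 0:
        seed_mask = np.zeros(len(verts), dtype=np.uint8)
        seed_mask[seed_v] = 1
        finite = dist[dist < 1e300]
        scale = finite.max() if len(finite) else 1.0
        dist = _relax_kernel(verts, tris, dist, seed_mask, relax_passes, 1e-9 * max(scale, 1.0))
    return dist
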