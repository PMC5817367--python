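"""Low-level vectorised geometry kernels shared by the pipeline stages.

Everything here operates on raw numpy arrays: points ``(n, 3)``, triangle
connectivity ``(m, 3)``.  Higher-level modules wrap these in the mesh data
model.  All routines are deterministic.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "weld_points",
    "triangle_areas",
    "segment_mesh_first_hit",
    "points_inside",
    "closest_point_on_surface",
    "plane_mesh_section",
]

# Fixed, irrational-ish ray direction for parity tests: avoids hitting mesh
# edges/vertices exactly on the axis-aligned fixtures used in practice.
_PARITY_DIR = np.array([0.2736128395, 0.5621348791, 0.7804231167])
_PARITY_DIR = _PARITY_DIR / np.linalg.norm(_PARITY_DIR)


def weld_points(points: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge points closer than ``tol``.

    Returns ``(unique_points, inverse)`` with ``unique_points[inverse]``
    recovering the input up to welding.  First occurrence (in input order)
    is the representative, so the output ordering is deterministic.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return points.reshape(0, 3), np.zeros(0, dtype=int)
    if tol <= 0:
        # exact dedup
        _, first, inverse = np.unique(
            points, axis=0, return_index=True, return_inverse=True
        )
        order = np.argsort(first)
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        return points[np.sort(first)], rank[inverse]
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    # union-find over proximity pairs
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n)])
    uniq_roots, inverse = np.unique(roots, return_inverse=True)
    return points[uniq_roots], inverse


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = vertices[triangles[:, 0]]
    b = vertices[triangles[:, 1]]
    c = vertices[triangles[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _moller_trumbore(
    origins: np.ndarray, directions: np.ndarray, v0, v1, v2, eps: float = 1e-12
):
    """Batched ray/triangle intersection.

    ``origins, directions``: (n, 3); ``v0, v1, v2``: (m, 3).
    Returns ``t`` of shape (n, m) with np.inf where there is no hit
    (t measured in units of ``directions``; only t >= -eps reported).
    """
    e1 = v1 - v0  # (m,3)
    e2 = v2 - v0
    d = directions[:, None, :]  # (n,1,3)
    p = np.cross(d, e2[None, :, :])  # (n,m,3)
    det = np.einsum("mk,nmk->nm", e1, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_det = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
        s = origins[:, None, :] - v0[None, :, :]
        u = np.einsum("nmk,nmk->nm", s, p) * inv_det
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("nmk,nmk->nm", q, d) * inv_det
        t = np.einsum("mk,nmk->nm", e2, q) * inv_det
    hit = (
        np.isfinite(t)
        & (u >= -1e-10)
        & (v >= -1e-10)
        & (u + v <= 1.0 + 1e-10)
        & (t >= -eps)
    )
    return np.where(hit, t, np.inf)


def segment_mesh_first_hit(
    starts: np.ndarray,
    ends: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    chunk: int = 2_000_000,
) -> np.ndarray:
    """First intersection parameter of each segment start->end with the mesh.

    Returns ``t`` in [0, 1] per segment, or np.nan where the segment misses
    the surface entirely.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    ends = np.atleast_2d(np.asarray(ends, dtype=float))
    v0 = vertices[triangles[:, 0]]
    v1 = vertices[triangles[:, 1]]
    v2 = vertices[triangles[:, 2]]
    n, m = len(starts), len(triangles)
    out = np.full(n, np.nan)
    step = max(1, chunk // max(m, 1))
    for i0 in range(0, n, step):
        i1 = min(n, i0 + step)
        t = _moller_trumbore(starts[i0:i1], ends[i0:i1] - starts[i0:i1], v0, v1, v2)
        tmin = t.min(axis=1)
        ok = tmin <= 1.0 + 1e-10
        out[i0:i1] = np.where(ok, np.clip(tmin, 0.0, 1.0), np.nan)
    return out


def points_inside(
    points: np.ndarray, vertices: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Ray-crossing parity containment test for a closed surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    v0 = vertices[triangles[:, 0]]
    v1 = vertices[triangles[:, 1]]
    v2 = vertices[triangles[:, 2]]
    dirs = np.broadcast_to(_PARITY_DIR, points.shape)
    n, m = len(points), len(triangles)
    inside = np.zeros(n, dtype=bool)
    step = max(1, 2_000_000 // max(m, 1))
    for i0 in range(0, n, step):
        i1 = min(n, i0 + step)
        t = _moller_trumbore(points[i0:i1], dirs[i0:i1], v0, v1, v2)
        crossings = np.sum(np.isfinite(t) & (t > 1e-12), axis=1)
        inside[i0:i1] = (crossings % 2) == 1
    return inside


def _point_segment_sq(p, a, b):
    """Squared distance point->segment, fully broadcast (…,3) arrays."""
    ab = b - a
    denom = np.einsum("...k,...k->...", ab, ab)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.einsum("...k,...k->...", p - a, ab) / denom
        t = np.where(denom > 0, np.clip(t, 0.0, 1.0), 0.0)
    proj = a + t[..., None] * ab
    d = p - proj
    return np.einsum("...k,...k->...", d, d), proj


def _point_triangle_sq(p, a, b, c):
    """Squared distance and closest point, point vs triangle, broadcast.

    Exact: min of the in-plane projection (when its barycentrics are
    non-negative) and the three edge segments.
    """
    n = np.cross(b - a, c - a)
    nn = np.einsum("...k,...k->...", n, n)
    ap = p - a
    with np.errstate(divide="ignore", invalid="ignore"):
        dist_plane = np.einsum("...k,...k->...", ap, n)
        proj = p - (dist_plane / np.where(nn > 0, nn, 1.0))[..., None] * n
    # barycentric test of the projection
    v0 = b - a
    v1 = c - a
    v2 = proj - a
    d00 = np.einsum("...k,...k->...", v0, v0)
    d01 = np.einsum("...k,...k->...", v0, v1)
    d11 = np.einsum("...k,...k->...", v1, v1)
    d20 = np.einsum("...k,...k->...", v2, v0)
    d21 = np.einsum("...k,...k->...", v2, v1)
    denom = d00 * d11 - d01 * d01
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (d11 * d20 - d01 * d21) / np.where(np.abs(denom) > 0, denom, 1.0)
        v = (d00 * d21 - d01 * d20) / np.where(np.abs(denom) > 0, denom, 1.0)
    interior = (np.abs(denom) > 1e-300) & (u >= 0) & (v >= 0) & (u + v <= 1)
    dp = p - proj
    sq_in = np.einsum("...k,...k->...", dp, dp)

    sq_ab, p_ab = _point_segment_sq(p, a, b)
    sq_bc, p_bc = _point_segment_sq(p, b, c)
    sq_ca, p_ca = _point_segment_sq(p, c, a)
    sq_edge = np.minimum(np.minimum(sq_ab, sq_bc), sq_ca)
    best_edge = np.where(
        (sq_ab <= sq_bc)[..., None] & (sq_ab <= sq_ca)[..., None],
        p_ab,
        np.where((sq_bc <= sq_ca)[..., None], p_bc, p_ca),
    )
    sq = np.where(interior, np.minimum(sq_in, sq_edge), sq_edge)
    closest = np.where((interior & (sq_in <= sq_edge))[..., None], proj, best_edge)
    return sq, closest


def closest_point_on_surface(
    points: np.ndarray,
    vertices: np.ndarray,
    triangles: np.ndarray,
    chunk: int = 4_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest point on a triangle surface for each query point.

    Brute force over all (point, triangle) pairs, chunked over points so the
    result is bit-identical to the naive double loop.
    Returns ``(distances, closest_points)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = vertices[triangles[:, 0]][None, :, :]
    b = vertices[triangles[:, 1]][None, :, :]
    c = vertices[triangles[:, 2]][None, :, :]
    n, m = len(points), len(triangles)
    dist = np.empty(n)
    closest = np.empty((n, 3))
    step = max(1, chunk // max(m, 1))
    for i0 in range(0, n, step):
        i1 = min(n, i0 + step)
        sq, cp = _point_triangle_sq(points[i0:i1, None, :], a, b, c)
        j = np.argmin(sq, axis=1)
        rows = np.arange(i1 - i0)
        dist[i0:i1] = np.sqrt(sq[rows, j])
        closest[i0:i1] = cp[rows, j]
    return dist, closest


def plane_mesh_section(
    vertices: np.ndarray,
    triangles: np.ndarray,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    tol: float = 1e-9,
) -> list[tuple[np.ndarray, bool]]:
    """Intersect a plane with a triangle mesh.

    Returns a list of ``(points, closed)`` chains: ordered (k, 3) arrays of
    section points, chained by endpoint proximity.
    """
    nrm = np.asarray(plane_normal, dtype=float)
    nrm = nrm / np.linalg.norm(nrm)
    sd = (vertices - np.asarray(plane_point, dtype=float)) @ nrm
    segs = []
    tv = triangles
    s = sd[tv]  # (m, 3)
    crossing = ~(np.all(s > tol, axis=1) | np.all(s < -tol, axis=1))
    for tri, sv in zip(tv[crossing], s[crossing]):
        pts = []
        for i in range(3):
            j = (i + 1) % 3
            si, sj = sv[i], sv[j]
            if (si > tol and sj < -tol) or (si < -tol and sj > tol):
                t = si / (si - sj)
                pts.append(vertices[tri[i]] + t * (vertices[tri[j]] - vertices[tri[i]]))
            elif abs(si) <= tol:
                pts.append(vertices[tri[i]])
        if len(pts) >= 2:
            # keep one segment per triangle (dedupe near-identical points)
            p = np.array(pts)
            keep = [0]
            for k in range(1, len(p)):
                if all(np.linalg.norm(p[k] - p[q]) > 10 * tol for q in keep):
                    keep.append(k)
            if len(keep) >= 2:
                segs.append((p[keep[0]], p[keep[1]]))
    if not segs:
        return []
    # chain segments into polylines by endpoint welding
    ends = np.array([[s0, s1] for s0, s1 in segs]).reshape(-1, 3)
    scale = max(np.ptp(ends, axis=0).max(), 1.0)
    uniq, inv = weld_points(ends, 1e-6 * scale)
    edges = inv.reshape(-1, 2)
    edges = edges[edges[:, 0] != edges[:, 1]]
    adj: dict[int, list[int]] = {}
    for a_, b_ in edges:
        adj.setdefault(int(a_), []).append(int(b_))
        adj.setdefault(int(b_), []).append(int(a_))
    visited_e = set()
    chains = []

    def walk(start: int, nxt: int) -> list[int]:
        path = [start, nxt]
        while True:
            prev, cur = path[-2], path[-1]
            cand = [w for w in adj[cur] if w != prev and (min(cur, w), max(cur, w)) not in visited_e]
            if not cand:
                return path
            w = cand[0]
            visited_e.add((min(cur, w), max(cur, w)))
            path.append(w)
            if w == path[0]:
                return path

    # open chains first (endpoints of degree 1), then loops
    degree = {k: len(v) for k, v in adj.items()}
    for node in sorted(adj):
        if degree[node] == 1:
            for nb in adj[node]:
                key = (min(node, nb), max(node, nb))
                if key not in visited_e:
                    visited_e.add(key)
                    path = walk(node, nb)
                    chains.append((uniq[path], False))
    for a_, b_ in edges:
        key = (min(a_, b_), max(a_, b_))
        if key not in visited_e:
            visited_e.add(key)
            path = walk(int(a_), int(b_))
            closed = path[0] == path[-1]
            pts = uniq[path[:-1]] if closed else uniq[path]
            chains.append((pts, closed))
    return chains
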