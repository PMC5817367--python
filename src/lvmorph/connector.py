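"""Connection band between the sac rim and the junction bottom border.

The sac's top border and the bifurcation-side border of the Y-junction are
built with the same number of nodes but not the same numbering.  The band
is one circumferential ring of quad-9 patches whose final CPs are: the two
borders (after renumbering) and an intermediate polyline of pairwise
midpoints projected onto the target surface.
"""
from __future__ import annotations

import numpy as np

from ._geom import closest_point_on_surface, weld_points
from ._patchwork import build_topology, evaluate_frame
from .mesh_core import (
    Polyline,
    QuadMesh,
    TriSurface,
    border_loops_indices,
    harmonize_orientation,
)

__all__ = [
    "align_borders",
    "intermediate_polyline",
    "mesh_band",
    "assemble_full",
]


def _pair_cost(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b, axis=1).sum())


def align_borders(
    border_a: Polyline, border_b: Polyline
) -> tuple[Polyline, Polyline]:
    """Renumber ``b`` to run parallel to ``a``.

    Minimizes the summed pairwise Euclidean distance over all cyclic
    rotations of ``b`` and both traversal directions; ties are broken in
    favour of the rotation starting nearest ``a``'s start, forward
    direction first.  ``a`` is returned unchanged.  Counts must match.
    """
    pa, pb = border_a.points, border_b.points
    K = len(pa)
    if K != len(pb):
        raise ValueError(
            f"border node counts differ: {K} vs {len(pb)}"
        )
    candidates = []
    for direction, seq in ((0, pb), (1, pb[::-1])):
        for k in range(K):
            rolled = np.roll(seq, -k, axis=0)
            cost = _pair_cost(pa, rolled)
            start_gap = float(np.linalg.norm(rolled[0] - pa[0]))
            candidates.append((cost, start_gap, direction, k, rolled))
    best = min(candidates, key=lambda c: (round(c[0], 12), round(c[1], 12), c[2], c[3]))
    return border_a, Polyline(best[4], closed=True)


def intermediate_polyline(
    a: Polyline, b: Polyline, surface: TriSurface
) -> Polyline:
    """Pairwise midpoints of two aligned borders, projected onto the surface."""
    if len(a) != len(b):
        raise ValueError("aligned borders must have equal counts")
    mids = 0.5 * (a.points + b.points)
    _, proj = closest_point_on_surface(mids, surface.vertices, surface.triangles)
    return Polyline(proj, closed=True)


def mesh_band(
    a: Polyline, mid: Polyline, b: Polyline, n_sub: int = 2
) -> QuadMesh:
    """One circumferential ring of quad-9 patches through three polylines.

    Rows are ``a`` (v=-1), ``mid`` (v=0) and ``b`` (v=+1); every pair of
    consecutive points around the ring forms one patch.  The count must be
    even (and >= 4) and ``n_sub`` even, so the band's border nodes coincide
    exactly with the input border nodes.
    """
    if not (len(a) == len(mid) == len(b)):
        raise ValueError("band polylines must share one point count")
    K = len(a)
    if K < 4 or K % 2:
        raise ValueError(f"band point count must be even and >= 4, got {K}")
    if n_sub % 2:
        raise ValueError("band n_sub must be even so border nodes interpolate")
    cps = np.concatenate([a.points, mid.points, b.points], axis=0)

    patch_grids = []
    for pc in range(K // 2):
        pg = np.empty((3, 3), dtype=np.int64)
        for s in range(3):  # circumferential
            col = (2 * pc + s) % K
            for t in range(3):  # a -> mid -> b
                pg[s, t] = t * K + col
        patch_grids.append(pg)
    patch_grids = np.asarray(patch_grids)
    topo = build_topology(patch_grids, cps, n_sub)
    return evaluate_frame(topo, patch_grids, cps)


def assemble_full(
    sac: QuadMesh,
    band: QuadMesh,
    junction: QuadMesh,
    weld_tol: float = 1e-6,
) -> QuadMesh:
    """Weld sac + band + junction into one conforming mesh.

    The shared borders must coincide within ``weld_tol`` (mm).  The result
    has exactly two border loops (the valve openings); a different census
    raises an assembly error.
    """
    verts = np.concatenate([sac.vertices, band.vertices, junction.vertices])
    offs = np.cumsum([0, len(sac.vertices), len(band.vertices)])
    quads = np.concatenate(
        [sac.quads + offs[0], band.quads + offs[1], junction.quads + offs[2]]
    )
    uniq, inverse = weld_points(verts, weld_tol)
    merged = harmonize_orientation(QuadMesh(uniq, inverse[quads]))
    loops = border_loops_indices(merged)
    if len(loops) != 2:
        # diagnose the worst unmatched pair among the expected shared borders
        worst = _worst_gap(sac, band, junction)
        raise ValueError(
            f"assembly produced {len(loops)} border loops instead of 2; "
            f"worst shared-border node gap {worst:.3g} mm exceeds weld_tol="
            f"{weld_tol:g}"
        )
    return merged


def _worst_gap(sac: QuadMesh, band: QuadMesh, junction: QuadMesh) -> float:
    """Largest nearest-node distance from band borders to sac/junction."""
    worst = 0.0
    for loop in border_loops_indices(band):
        pts = band.vertices[loop]
        best = np.inf
        for other in (sac, junction):
            d = np.linalg.norm(
                pts[:, None, :] - other.vertices[None, :, :], axis=2
            ).min(axis=1)
            best = min(best, float(d.max()))
        worst = max(worst, best)
    return worst
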