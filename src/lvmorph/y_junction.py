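"""Structured meshing of the upper left heart as a two-conduit bifurcation.

The left atrium and aortic root sit so close together that sac-style radial
morphing would let nodes cross the thin wall between them, so the region is
meshed as a vessel bifurcation instead:

1. two saddle points picked on the ridge separating the conduits define a
   cutting plane (ridge direction x vertical); its intersection with the
   surface, trimmed between the saddles, is the *ridge polyline* — the
   shared wall crest;
2. per conduit, a closed *bifurcation ring* is formed by the ridge plus a
   horizontal semicircle radially projected onto the surface;
3. an epsilon-radius circle at each valve centroid, with matching point
   count, marks the far end of the conduit; N intermediate rings are linear
   interpolations between a concentrically scaled-down bifurcation ring and
   the valve circle;
4. every ring is enlarged concentrically until it clears the surface, and
   each grid point is projected along its small->large segment onto the
   wall (first crossing);
5. the resulting (N+2) x K on-surface grid per conduit supplies the final
   CPs of the quad-9 isoparametric patches.

Only the two saddle points are manual input (frame 0); subsequent frames
reuse landmarks tracked by nearest-point mapping.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geom import (
    closest_point_on_surface,
    plane_mesh_section,
    points_inside,
    segment_mesh_first_hit,
)
from ._patchwork import build_topology, evaluate_frame
from .mesh_core import Polyline, QuadMesh, TriSurface, capped
from .sac_morph import ProjectionQualityError

__all__ = [
    "JunctionLandmarks",
    "JunctionScaffold",
    "ConduitCPGrid",
    "build_ridge",
    "build_scaffold",
    "project_conduit_rings",
    "mesh_junction",
    "track_landmarks",
    "LandmarkError",
]


class LandmarkError(ValueError):
    """Landmarks inconsistent with the surface geometry."""


@dataclass
class JunctionLandmarks:
    """Manually supplied geometry anchors of the bifurcation."""

    saddle_points: np.ndarray  # (2, 3), on the inter-conduit ridge
    valve_centroids: np.ndarray  # (2, 3): mitral, aortic
    vertical_dir: np.ndarray  # unit vector, apex->base sense
    conduit_length: float | None = None  # mm; default: centroid distance

    def __post_init__(self):
        self.saddle_points = np.asarray(self.saddle_points, float).reshape(2, 3)
        self.valve_centroids = np.asarray(self.valve_centroids, float).reshape(2, 3)
        v = np.asarray(self.vertical_dir, float).reshape(3)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("vertical_dir must be nonzero")
        self.vertical_dir = v / nrm
        if np.linalg.norm(self.saddle_points[1] - self.saddle_points[0]) < 1e-9:
            raise LandmarkError("saddle points coincide")


@dataclass
class JunctionScaffold:
    """Small/large ring ladder of both conduits before surface projection."""

    ridge: Polyline
    bifurcation_center: np.ndarray
    rings_small: list[np.ndarray]  # per conduit: (N+2, K, 3)
    rings_large: list[np.ndarray]  # per conduit: (N+2, K, 3)
    bifurcation_rings: list[np.ndarray]  # per conduit: (K, 3) on-surface row 0
    n_ridge: int  # ridge points per ring (shared-wall portion)
    N: int

    @property
    def K(self) -> int:
        return self.rings_small[0].shape[1]


@dataclass
class ConduitCPGrid:
    """On-surface CP grids, one (N+2) x K array per conduit."""

    grids: list[np.ndarray]
    n_ridge: int

    @property
    def K(self) -> int:
        return self.grids[0].shape[1]

    @property
    def n_rows(self) -> int:
        return self.grids[0].shape[0]


# ---------------------------------------------------------------------------
# ridge
# ---------------------------------------------------------------------------

def build_ridge(
    landmarks: JunctionLandmarks,
    surface: TriSurface,
    max_saddle_distance: float = 2.0,
) -> Polyline:
    """Intersection curve of the saddle plane with the surface, between saddles.

    The plane is spanned by the saddle-to-saddle direction and the vertical
    direction.  On a closed section curve the shorter arc between the two
    saddle points is taken (the crest between the conduits).
    """
    s1, s2 = landmarks.saddle_points
    d, _ = closest_point_on_surface(
        np.vstack([s1, s2]), surface.vertices, surface.triangles
    )
    if d.max() > max_saddle_distance:
        raise LandmarkError(
            f"saddle point {d.max():.2f} mm from the surface "
            f"(limit {max_saddle_distance} mm)"
        )
    span = s2 - s1
    normal = np.cross(span, landmarks.vertical_dir)
    if np.linalg.norm(normal) < 1e-9 * np.linalg.norm(span):
        raise LandmarkError("saddle direction is parallel to vertical_dir")
    chains = plane_mesh_section(surface.vertices, surface.triangles, s1, normal)
    if not chains:
        raise LandmarkError("saddle plane does not intersect the surface")

    def chain_cost(pts: np.ndarray) -> float:
        d1 = np.linalg.norm(pts - s1, axis=1).min()
        d2 = np.linalg.norm(pts - s2, axis=1).min()
        return d1 + d2

    pts, closed = min(chains, key=lambda ch: chain_cost(ch[0]))
    i1 = int(np.argmin(np.linalg.norm(pts - s1, axis=1)))
    i2 = int(np.argmin(np.linalg.norm(pts - s2, axis=1)))
    if i1 == i2:
        raise LandmarkError("saddle points map to the same section point")
    if not closed:
        lo, hi = min(i1, i2), max(i1, i2)
        arc = pts[lo : hi + 1]
        if i1 > i2:
            arc = arc[::-1]
    else:
        # two candidate arcs around the loop; keep the shorter
        n = len(pts)
        fwd = [(i1 + k) % n for k in range((i2 - i1) % n + 1)]
        bwd = [(i1 - k) % n for k in range((i1 - i2) % n + 1)]

        def arclen(idx):
            p = pts[idx]
            return np.linalg.norm(np.diff(p, axis=0), axis=1).sum()

        arc = pts[fwd] if arclen(fwd) <= arclen(bwd) else pts[bwd]
    if len(arc) < 2:
        raise LandmarkError("degenerate ridge between saddle points")
    return Polyline(arc, closed=False)


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

def _axis_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = int(np.argmin(np.abs(axis)))
    e = np.zeros(3)
    e[k] = 1.0
    u1 = np.cross(axis, e)
    u1 /= np.linalg.norm(u1)
    return u1, np.cross(axis, u1)


def _bifurcation_ring(
    ridge_pts: np.ndarray,
    side_point: np.ndarray,
    vertical: np.ndarray,
    surface: TriSurface,
    k_semi: int,
) -> np.ndarray:
    """Closed ring: ridge + horizontal semicircle radially projected on-wall.

    ``side_point`` (the conduit's valve centroid) selects on which side of
    the ridge the semicircle bulges.
    """
    a, b = ridge_pts[0], ridge_pts[-1]
    c0 = 0.5 * (a + b)
    e1 = b - c0
    e2 = np.cross(vertical, e1)
    nrm = np.linalg.norm(e2)
    if nrm < 1e-12:
        raise LandmarkError("ridge endpoints aligned with vertical_dir")
    e2 = e2 / nrm * np.linalg.norm(e1)
    if np.dot(e2, side_point - c0) < 0:
        e2 = -e2
    theta = np.linspace(0.0, np.pi, k_semi)[1:-1]  # interior nodes only
    semi = c0 + np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
    # radial projection from the ring center onto the surface
    scale = max(np.linalg.norm(e1) * 20.0, 10.0)
    dirs = semi - c0
    dirs = dirs / np.linalg.norm(dirs, axis=1)[:, None]
    t = segment_mesh_first_hit(
        np.repeat(c0[None], len(semi), axis=0),
        c0 + dirs * scale,
        surface.vertices,
        surface.triangles,
    )
    proj = c0 + dirs * (t[:, None] * scale)
    miss = ~np.isfinite(t)
    if miss.any():
        _, near = closest_point_on_surface(
            semi[miss], surface.vertices, surface.triangles
        )
        proj[miss] = near
    return np.vstack([ridge_pts, proj])


def build_scaffold(
    landmarks: JunctionLandmarks,
    ridge: Polyline,
    surface: TriSurface,
    N: int = 3,
    epsilon: float = 0.1,
    k_ridge: int = 5,
    k_semi: int = 5,
    ring0_scale: float = 0.5,
    max_scale_up: float = 10.0,
) -> JunctionScaffold:
    """Build the small/large ring ladders of both conduits.

    Per conduit: row 0 is the bifurcation ring scaled down by
    ``ring0_scale``, row ``N+1`` the epsilon circle at the valve position,
    rows 1..N linear interpolations.  Large rings enlarge each small ring
    concentrically to a common absolute radius, doubled geometrically from
    1.2x the bifurcation-ring radius until every point clears the surface
    (parity test), capped at ``max_scale_up``x.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if k_ridge < 3 or k_semi < 3:
        raise ValueError("k_ridge and k_semi must be >= 3")
    ridge_pts = ridge.resample(k_ridge).points
    closed_surface = capped(surface)
    vertical = landmarks.vertical_dir
    bif_center = 0.5 * (ridge_pts[0] + ridge_pts[-1])

    rings_small, bif_rings = [], []
    ring_radius = 0.0
    for i in range(2):
        vc = landmarks.valve_centroids[i]
        rp = ridge_pts if i == 0 else ridge_pts[::-1]
        ring0 = _bifurcation_ring(rp, vc, vertical, surface, k_semi)
        bif_rings.append(ring0)
        c_ring = ring0.mean(axis=0)
        ring_radius = max(
            ring_radius, float(np.linalg.norm(ring0 - c_ring, axis=1).max())
        )
        axis = vc - bif_center
        length = landmarks.conduit_length or float(np.linalg.norm(axis))
        axis_dir = axis / np.linalg.norm(axis)
        valve_pos = bif_center + axis_dir * length
        u1, u2 = _axis_frame(axis_dir)
        # valve circle nodes phased like the bifurcation ring about the axis
        rel = ring0 - c_ring
        phi = np.arctan2(rel @ u2, rel @ u1)
        valve_ring = valve_pos + epsilon * (
            np.outer(np.cos(phi), u1) + np.outer(np.sin(phi), u2)
        )
        small0 = c_ring + ring0_scale * (ring0 - c_ring)
        t = (np.arange(N + 2) / (N + 1))[:, None, None]
        rings_small.append((1 - t) * small0[None] + t * valve_ring[None])

    # common outer radius: geometric doubling of the multiplier from 1.2
    factor = 1.2
    rings_large = None
    while factor <= max_scale_up + 1e-9:
        radius = factor * ring_radius
        cand = []
        for rs in rings_small:
            centers = rs.mean(axis=1, keepdims=True)
            rel = rs - centers
            nrm = np.linalg.norm(rel, axis=2, keepdims=True)
            cand.append(centers + rel / np.where(nrm > 0, nrm, 1.0) * radius)
        pts = np.concatenate([c.reshape(-1, 3) for c in cand], axis=0)
        if not points_inside(
            pts, closed_surface.vertices, closed_surface.triangles
        ).any():
            rings_large = cand
            break
        factor *= 2.0
    if rings_large is None:
        raise LandmarkError(
            f"no concentric scale-up within {max_scale_up}x clears the surface"
        )
    return JunctionScaffold(
        ridge=Polyline(ridge_pts),
        bifurcation_center=bif_center,
        rings_small=rings_small,
        rings_large=rings_large,
        bifurcation_rings=bif_rings,
        n_ridge=k_ridge,
        N=N,
    )


def project_conduit_rings(
    scaffold: JunctionScaffold,
    surface: TriSurface,
    max_fallback_fraction: float = 0.10,
) -> ConduitCPGrid:
    """Project every scaffold grid point onto the surface.

    Each CP is the first intersection of its small->large segment with the
    wall; misses fall back to the nearest surface point with a warning.  Row
    0 is pinned to the exact on-surface bifurcation ring so the shared ridge
    CPs of the two conduits stay bitwise identical (conformity at the weld).
    """
    grids = []
    n_total = n_fallback = 0
    for rs, rl, ring0 in zip(
        scaffold.rings_small, scaffold.rings_large, scaffold.bifurcation_rings
    ):
        shp = rs.shape
        starts = rs.reshape(-1, 3)
        ends = rl.reshape(-1, 3)
        t = segment_mesh_first_hit(starts, ends, surface.vertices, surface.triangles)
        proj = starts + t[:, None] * (ends - starts)
        miss = ~np.isfinite(t)
        if miss.any():
            _, near = closest_point_on_surface(
                starts[miss], surface.vertices, surface.triangles
            )
            proj[miss] = near
        grid = proj.reshape(shp)
        grid[0] = ring0
        n_total += starts.shape[0] - shp[1]  # row 0 pinned, not projected
        n_fallback += int(miss.reshape(shp[:2])[1:].sum())
        grids.append(grid)
    if n_fallback:
        warnings.warn(
            f"{n_fallback}/{n_total} conduit CPs used the nearest-point fallback",
            stacklevel=2,
        )
        if n_fallback > max_fallback_fraction * n_total:
            raise ProjectionQualityError(
                f"{n_fallback}/{n_total} conduit CPs needed the fallback; "
                "check the junction landmarks"
            )
    return ConduitCPGrid(grids, scaffold.n_ridge)


def mesh_junction(grid: ConduitCPGrid, n_sub: int) -> QuadMesh:
    """Tile both conduit grids with quad-9 patches and weld into one mesh.

    Requires an odd row count >= 3 and an even circumferential count >= 4
    (every 2x2 block of grid points forms one patch's 9 CPs, wrapping
    around the ring).
    """
    rows, K = grid.n_rows, grid.K
    if rows < 3 or rows % 2 == 0:
        raise ValueError(
            f"conduit grid needs an odd number of rows >= 3, got {rows} "
            "(choose an odd N)"
        )
    if K < 4 or K % 2:
        raise ValueError(
            f"conduit ring point count must be even and >= 4, got {K}"
        )
    all_cps = []
    all_patches = []
    offset = 0
    for g in grid.grids:
        cps = g.reshape(-1, 3)

        def node(r: int, c: int) -> int:
            return offset + r * K + (c % K)

        for pr in range((rows - 1) // 2):
            for pc in range(K // 2):
                pg = np.empty((3, 3), dtype=np.int64)
                for s in range(3):  # circumferential
                    for t in range(3):  # axial
                        pg[s, t] = node(2 * pr + t, 2 * pc + s)
                all_patches.append(pg)
        all_cps.append(cps)
        offset += len(cps)
    cps = np.concatenate(all_cps, axis=0)
    # weld the shared ridge CPs (bitwise equal by construction)
    from ._geom import weld_points

    scale = max(float(np.ptp(cps, axis=0).max()), 1.0)
    uniq, inverse = weld_points(cps, 1e-9 * scale)
    patch_grids = inverse[np.asarray(all_patches)]
    topo = build_topology(patch_grids, uniq, n_sub)
    return evaluate_frame(topo, patch_grids, uniq)


def track_landmarks(
    landmarks: JunctionLandmarks,
    next_surface: TriSurface,
    current_surface: TriSurface | None = None,
    max_jump: float = 10.0,
) -> JunctionLandmarks:
    """Carry the frame-0 landmarks to the next frame.

    Saddle points lie on the surface and map to their nearest points on the
    next frame.  A valve centroid is an orifice center (an interior point);
    when ``current_surface`` is given it is advected by the motion of its
    nearest wall point (nearest-on-next minus nearest-on-current), which
    keeps it off the wall; without a current surface it is nearest-point
    mapped like the saddles.
    """
    sp = landmarks.saddle_points
    vc = landmarks.valve_centroids
    d_s, near_s = closest_point_on_surface(
        sp, next_surface.vertices, next_surface.triangles
    )
    if current_surface is None:
        d_v, new_vc = closest_point_on_surface(
            vc, next_surface.vertices, next_surface.triangles
        )
    else:
        _, q_cur = closest_point_on_surface(
            vc, current_surface.vertices, current_surface.triangles
        )
        d_v, q_next = closest_point_on_surface(
            q_cur, next_surface.vertices, next_surface.triangles
        )
        new_vc = vc + (q_next - q_cur)
    if max(d_s.max(), d_v.max()) > max_jump:
        raise LandmarkError(
            "landmark tracking lost: nearest surface point "
            f"{max(d_s.max(), d_v.max()):.1f} mm away"
        )
    return JunctionLandmarks(
        saddle_points=near_s,
        valve_centroids=new_vc,
        vertical_dir=landmarks.vertical_dir,
        conduit_length=landmarks.conduit_length,
    )
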