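"""Mesh quality, reconstruction accuracy and physiological quantities.

Quality is the equiangle skewness

    Qeas = max( (theta_max - theta_e) / (180 - theta_e),
                (theta_e - theta_min) / theta_e )

with ``theta_e = 90`` degrees for quadrilaterals: 0 for a perfect right-
angled element, 1 for a fully degenerate one.  The CFD-practice gate is
max Qeas <= 0.9 and mean Qeas <= 0.25 per frame.  Corner angles are
measured between adjacent edges of the linear (corner-node) element, as a
CFD solver sees the exported mesh.

Accuracy is the unsigned nearest-point distance of every mesh node to the
segmented target surface, classified into 6 intervals starting at 1/1000
mm, plus the volume percentage difference against the segmented geometry.

Physiology: per-frame chamber volume, ejection fraction
EF = (EDV - ESV) / EDV with EDV/ESV the max/min frame volume, and the
apex-to-bifurcation-center distance over the cycle (well-defined because
all frames share one connectivity).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import closest_point_on_surface
from .mesh_core import Mesh4D, QuadMesh, TriSurface, closed_volume

__all__ = [
    "SkewnessReport",
    "DistanceReport",
    "PhysioReport",
    "per_element_skewness",
    "equiangle_skewness",
    "distance_errors",
    "volume_pct_difference",
    "ejection_fraction",
    "apex_bifurcation_distance",
    "quality_gate",
    "physio_report",
    "DEFAULT_BIN_EDGES",
    "MAX_SKEW_THRESHOLD",
    "MEAN_SKEW_THRESHOLD",
]

MAX_SKEW_THRESHOLD = 0.9
MEAN_SKEW_THRESHOLD = 0.25
THETA_E = 90.0

# interior edges (mm) of the 6 distance intervals: the lowest edge is fixed
# at 1/1000 mm; 0.35 is a typical CT pixel size, 1 mm the coarse threshold
DEFAULT_BIN_EDGES = (0.001, 0.01, 0.1, 0.35, 1.0)


def per_element_skewness(vertices: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Equiangle skewness per element from the 4 corner angles.

    Elements with a zero-length edge are flagged with Qeas = 1.
    """
    p = vertices[quads]  # (m, 4, 3)
    prev = np.roll(p, 1, axis=1) - p
    nxt = np.roll(p, -1, axis=1) - p
    ln_p = np.linalg.norm(prev, axis=2)
    ln_n = np.linalg.norm(nxt, axis=2)
    degenerate = (ln_p < 1e-300) | (ln_n < 1e-300)
    cross = np.linalg.norm(np.cross(prev, nxt), axis=2)
    dot = np.einsum("mkj,mkj->mk", prev, nxt)
    angles = np.degrees(np.arctan2(cross, dot))
    angles = np.where(degenerate, np.nan, angles)
    with np.errstate(invalid="ignore"):
        tmax = np.nanmax(np.where(degenerate, -np.inf, angles), axis=1)
        tmin = np.nanmin(np.where(degenerate, np.inf, angles), axis=1)
        q = np.maximum(
            (tmax - THETA_E) / (180.0 - THETA_E), (THETA_E - tmin) / THETA_E
        )
    q = np.where(degenerate.any(axis=1), 1.0, np.clip(q, 0.0, 1.0))
    return q


@dataclass
class SkewnessReport:
    per_element: np.ndarray
    max: float
    mean: float
    histogram: np.ndarray  # counts per 0.1-wide bin over [0, 1]
    max_thresh: float
    mean_thresh: float

    @property
    def passes(self) -> bool:
        return self.max <= self.max_thresh and self.mean <= self.mean_thresh


def equiangle_skewness(
    mesh: QuadMesh,
    max_thresh: float = MAX_SKEW_THRESHOLD,
    mean_thresh: float = MEAN_SKEW_THRESHOLD,
) -> SkewnessReport:
    """Per-element equiangle skewness with the CFD pass thresholds."""
    q = per_element_skewness(mesh.vertices, mesh.quads)
    hist, _ = np.histogram(q, bins=np.linspace(0.0, 1.0, 11))
    return SkewnessReport(
        per_element=q,
        max=float(q.max()) if len(q) else 0.0,
        mean=float(q.mean()) if len(q) else 0.0,
        histogram=hist,
        max_thresh=max_thresh,
        mean_thresh=mean_thresh,
    )


@dataclass
class DistanceReport:
    per_node: np.ndarray  # mm
    bin_edges: np.ndarray  # full 7-edge vector (0, interior..., inf)
    counts: np.ndarray  # 6 interval counts
    max: float
    reference_length: float
    fraction_below_reference: float


def distance_errors(
    mesh: QuadMesh,
    target: TriSurface,
    bin_edges=DEFAULT_BIN_EDGES,
    reference_length: float = 1.0,
) -> DistanceReport:
    """Nearest-point distance of every mesh node to the target surface.

    Exact point-to-triangle distances (results identical to the brute-force
    all-pairs minimum), classified into the 6 intervals bounded by the 5
    interior ``bin_edges``; the share of nodes below ``reference_length``
    (pixel size or 1 mm) is reported.
    """
    if len(mesh.vertices) == 0 or len(target.triangles) == 0:
        raise ValueError("distance_errors needs a non-empty mesh and target")
    edges = np.asarray(bin_edges, dtype=float).ravel()
    if len(edges) != 5 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be 5 increasing interior edges")
    d, _ = closest_point_on_surface(
        mesh.vertices, target.vertices, target.triangles
    )
    full = np.concatenate([[0.0], edges, [np.inf]])
    counts, _ = np.histogram(d, bins=full)
    return DistanceReport(
        per_node=d,
        bin_edges=full,
        counts=counts,
        max=float(d.max()),
        reference_length=reference_length,
        fraction_below_reference=float(np.mean(d < reference_length)),
    )


def volume_pct_difference(mapped, segmented) -> float:
    """100 * |V_mapped - V_segmented| / V_segmented, border loops capped."""
    v_map = closed_volume(mapped, cap_borders=True)
    v_seg = closed_volume(segmented, cap_borders=True)
    if v_seg <= 0:
        raise ValueError("segmented geometry has nonpositive volume")
    return 100.0 * abs(v_map - v_seg) / v_seg


def ejection_fraction(volumes) -> float:
    """EF = (EDV - ESV) / EDV with EDV = max and ESV = min frame volume."""
    v = np.asarray(volumes, dtype=float).ravel()
    if len(v) < 2:
        raise ValueError("ejection fraction needs at least 2 volumes")
    if np.any(v <= 0):
        raise ValueError("all volumes must be positive")
    return float((v.max() - v.min()) / v.max())


def apex_bifurcation_distance(
    mesh4d: Mesh4D,
    apex_node_index: int,
    bifurcation_center_per_frame,
) -> np.ndarray:
    """Per-frame distance between the apex node and the bifurcation center.

    The apex is a fixed node index (the template apex CP), valid in every
    frame thanks to the 1-to-1 vertex correspondence.
    """
    centers = np.asarray(bifurcation_center_per_frame, dtype=float).reshape(-1, 3)
    if len(centers) != len(mesh4d.frames):
        raise ValueError("one bifurcation center per frame is required")
    n = len(mesh4d.frames[0].vertices)
    if not (0 <= apex_node_index < n):
        raise IndexError(f"apex node index {apex_node_index} out of range 0..{n-1}")
    apex = np.array([f.vertices[apex_node_index] for f in mesh4d.frames])
    return np.linalg.norm(apex - centers, axis=1)


def quality_gate(
    mesh4d: Mesh4D,
    max_thresh: float = MAX_SKEW_THRESHOLD,
    mean_thresh: float = MEAN_SKEW_THRESHOLD,
) -> tuple[bool, list[SkewnessReport]]:
    """A 4D mesh passes iff every frame meets both skewness thresholds."""
    reports = [
        equiangle_skewness(f, max_thresh, mean_thresh) for f in mesh4d.frames
    ]
    return all(r.passes for r in reports), reports


@dataclass
class PhysioReport:
    volumes: np.ndarray  # mm^3 per frame
    ef: float
    apex_bifurcation: np.ndarray | None = None  # mm per frame
    volume_pct_diff: np.ndarray | None = None  # % per frame vs segmented
    times: np.ndarray | None = None


def physio_report(
    mesh4d: Mesh4D,
    segmented: list[TriSurface] | None = None,
    apex_node_index: int | None = None,
    bifurcation_center_per_frame=None,
) -> PhysioReport:
    """Volume curve, EF and (optionally) distances/volume differences."""
    volumes = np.array(
        [closed_volume(f, cap_borders=True) for f in mesh4d.frames]
    )
    ef = ejection_fraction(volumes)
    pct = None
    if segmented is not None:
        if len(segmented) != len(mesh4d.frames):
            raise ValueError("one segmented surface per frame is required")
        pct = np.array(
            [
                volume_pct_difference(f, s)
                for f, s in zip(mesh4d.frames, segmented)
            ]
        )
    dist = None
    if apex_node_index is not None and bifurcation_center_per_frame is not None:
        dist = apex_bifurcation_distance(
            mesh4d, apex_node_index, bifurcation_center_per_frame
        )
    return PhysioReport(
        volumes=volumes,
        ef=ef,
        apex_bifurcation=dist,
        volume_pct_diff=pct,
        times=mesh4d.times.copy(),
    )
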