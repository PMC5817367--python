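"""Deterministic synthetic 4D geometries with analytic ground truth.

Patient imaging data cannot be redistributed, so every pipeline stage is
exercised on generated stand-ins:

* :func:`make_breathing_sac` — a truncated half-ellipsoid "ventricle"
  (open at the base plane) whose semi-axes follow a smooth periodic volume
  curve hitting a prescribed ejection fraction exactly, with optional
  seeded surface-normal noise emulating segmentation roughness;
* :func:`make_bifurcation_target` — a dome (sphere) with two outgoing
  tubes, built as an implicit union and extracted with marching cubes,
  standing in for the left-atrium/aorta bifurcation, with analytic
  landmarks;
* :func:`make_pointcloud` — seeded uniform-area sampling of a surface plus
  a Delaunay-style triangulation (convex hull of ray directions about the
  centroid; valid for the star-shaped geometries used here), emulating
  manually segmented ultrasound point clouds.

All generators are pure functions of their arguments including the seed.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

from .mesh_core import TriSurface

__all__ = [
    "make_breathing_sac",
    "make_bifurcation_target",
    "make_pointcloud",
    "half_ellipsoid",
]


def half_ellipsoid(
    radii, n_theta: int = 24, n_phi: int = 48, center=(0.0, 0.0, 0.0)
) -> TriSurface:
    """Triangulated half-ellipsoid, apex at ``-c z``, open at the z=0 plane."""
    a, b, c = radii
    cx = np.asarray(center, dtype=float)
    verts = [cx + np.array([0.0, 0.0, -c])]
    for i in range(1, n_theta + 1):
        th = np.pi / 2 * i / n_theta  # polar angle from the apex
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        ring = np.column_stack(
            [
                a * np.sin(th) * np.cos(phi),
                b * np.sin(th) * np.sin(phi),
                -c * np.cos(th) * np.ones(n_phi),
            ]
        )
        verts.append(cx + ring)
    vertices = np.vstack([verts[0][None], *verts[1:]])
    tris = []
    for j in range(n_phi):  # apex fan
        tris.append([0, 1 + j, 1 + (j + 1) % n_phi])
    for i in range(n_theta - 1):  # quad strips
        r0 = 1 + i * n_phi
        r1 = r0 + n_phi
        for j in range(n_phi):
            j1 = (j + 1) % n_phi
            tris.append([r0 + j, r1 + j, r1 + j1])
            tris.append([r0 + j, r1 + j1, r0 + j1])
    return TriSurface(vertices, np.array(tris))


def _half_ellipsoid_volume(radii) -> float:
    a, b, c = radii
    return 2.0 / 3.0 * np.pi * a * b * c


def make_breathing_sac(
    n_frames: int = 15,
    base_radii=(25.0, 22.0, 45.0),
    ef_target: float = 0.58,
    noise_sigma: float = 0.0,
    n_theta: int = 24,
    n_phi: int = 48,
    seed: int = 0,
) -> tuple[list[TriSurface], dict]:
    """Half-ellipsoid sac breathing through one cardiac cycle.

    The volume curve is ``V(T) = V_ED * (1 - EF * (1 - cos 2 pi T) / 2)``:
    maximal (end-diastole) at T = 0, minimal at T = 0.5, periodic, with the
    analytic EF equal to ``ef_target`` exactly.  All semi-axes scale by
    ``(V/V_ED)^(1/3)`` per frame.  Noise is Gaussian along the outward
    surface normal, drawn frame by frame from one seeded generator.

    Returns the frame surfaces and a ground-truth dict: per-frame analytic
    ``volumes`` (mm^3, noise-free), ``ef``, ``apex_points``, ``times``,
    ``scales``, ``base_centroid`` and ``base_radii``.
    """
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3")
    if not (0 < ef_target < 1):
        raise ValueError("ef_target must be in (0, 1)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    a, b, c = (float(r) for r in base_radii)
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) / n_frames
    v_ed = _half_ellipsoid_volume((a, b, c))
    # cosine envelope, renormalised over the sampled grid so the extreme
    # frames realise ef_target exactly even when no frame sits at T = 0.5
    envelope = (1.0 - np.cos(2 * np.pi * times)) / 2.0
    envelope = envelope / envelope.max()
    volumes = v_ed * (1.0 - ef_target * envelope)
    scales = (volumes / v_ed) ** (1.0 / 3.0)
    frames = []
    apex_points = []
    for s in scales:
        radii = (a * s, b * s, c * s)
        surf = half_ellipsoid(radii, n_theta=n_theta, n_phi=n_phi)
        if noise_sigma > 0:
            v = surf.vertices
            # outward normal of the ellipsoid implicit surface
            grad = 2 * v / np.array(radii) ** 2
            grad[:, 2] = np.where(v[:, 2] > -1e-12, 0.0, grad[:, 2])  # rim: radial only
            nrm = np.linalg.norm(grad, axis=1, keepdims=True)
            grad = grad / np.where(nrm > 0, nrm, 1.0)
            v = v + noise_sigma * rng.standard_normal((len(v), 1)) * grad
            surf = TriSurface(v, surf.triangles)
        frames.append(surf)
        apex_points.append(np.array([0.0, 0.0, -c * s]))
    truth = {
        "volumes": volumes,
        "ef": float(ef_target),
        "apex_points": np.array(apex_points),
        "times": times,
        "scales": scales,
        "base_centroid": np.zeros(3),
        "base_radii": np.array([a, b, c]),
    }
    return frames, truth


def make_bifurcation_target(
    dome_radius: float = 20.0,
    tube_radii=(6.0, 6.0),
    tube_offsets=(-8.0, 8.0),
    tube_top: float = 34.0,
    valve_height: float = 28.0,
    voxel: float = 1.2,
    scale: float = 1.0,
) -> tuple[TriSurface, dict]:
    """Dome with two vertical tubes: the Y-junction stand-in.

    A sphere of ``dome_radius`` centred at the origin is united with two
    vertical cylinders of radii ``tube_radii`` at ``x = tube_offsets``,
    capped at ``tube_top``; the implicit union is extracted by marching
    cubes at ``voxel`` resolution (the faceting control).  ``scale``
    uniformly scales everything — handy for emulating a beating frame
    sequence with tracked landmarks.

    Returns the surface and analytic landmarks: two ``saddle_points`` on
    the inter-tube ridge (the sphere arc in the x = 0 plane), the
    ``valve_centroids`` on the tube axes at ``valve_height``, the
    ``bifurcation_center`` (saddle midpoint) and the tube axes/radii.
    """
    from skimage.measure import marching_cubes  # heavy import, keep local

    r1, r2 = tube_radii
    d1, d2 = tube_offsets
    if d2 - d1 <= r1 + r2:
        raise ValueError("tubes overlap: increase offsets or shrink radii")
    if not (dome_radius * 0.5 < valve_height < tube_top):
        raise ValueError("valve_height must lie between the dome and tube top")
    R = dome_radius
    pad = 3.0 * voxel
    lo = np.array([-(R + pad), -(R + pad), -(R + pad)])
    hi = np.array([R + pad, R + pad, tube_top + pad])
    nx, ny, nz = (np.ceil((hi - lo) / voxel).astype(int) + 1)
    xs = np.linspace(lo[0], hi[0], nx)
    ys = np.linspace(lo[1], hi[1], ny)
    zs = np.linspace(lo[2], hi[2], nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    sphere = np.sqrt(X**2 + Y**2 + Z**2) - R

    def tube(dx: float, r: float) -> np.ndarray:
        radial = np.sqrt((X - dx) ** 2 + Y**2) - r
        # cap: bottom end buried inside the sphere, top at tube_top
        return np.maximum(radial, np.maximum(Z - tube_top, (R * 0.3) - Z))

    sdf = np.minimum(sphere, np.minimum(tube(d1, r1), tube(d2, r2)))
    spacing = (xs[1] - xs[0], ys[1] - ys[0], zs[1] - zs[0])
    verts, faces, _, _ = marching_cubes(sdf, level=0.0, spacing=spacing)
    verts = verts + lo
    surf = TriSurface(verts * scale, faces)

    y_s = 0.5 * (d2 - d1)
    z_s = np.sqrt(R**2 - y_s**2)
    saddles = np.array([[0.0, -y_s, z_s], [0.0, y_s, z_s]]) * scale
    valves = np.array([[d1, 0.0, valve_height], [d2, 0.0, valve_height]]) * scale
    landmarks = {
        "saddle_points": saddles,
        "valve_centroids": valves,
        "bifurcation_center": saddles.mean(axis=0),
        "vertical_dir": np.array([0.0, 0.0, 1.0]),
        "tube_axes": np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]]),
        "tube_radii": np.array([r1, r2]) * scale,
        "tube_offsets": np.array([d1, d2]) * scale,
    }
    return surf, landmarks


def make_pointcloud(
    surface: TriSurface, n_points: int, seed: int = 0
) -> tuple[np.ndarray, TriSurface]:
    """Uniform-area point sampling plus a Delaunay-style reconstruction.

    Points are drawn by area-weighted triangle choice and uniform
    barycentric placement.  The triangulation connects the sampled points
    through the convex hull of their unit directions about the centroid
    (a spherical Delaunay), which is valid for the star-shaped chamber
    geometries this package targets.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    rng = np.random.default_rng(seed)
    v, t = surface.vertices, surface.triangles
    areas = np.linalg.norm(
        np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
    )
    probs = areas / areas.sum()
    choice = rng.choice(len(t), size=n_points, p=probs)
    u = rng.random((n_points, 2))
    flip = u.sum(axis=1) > 1
    u[flip] = 1 - u[flip]
    tri = t[choice]
    pts = (
        v[tri[:, 0]]
        + u[:, :1] * (v[tri[:, 1]] - v[tri[:, 0]])
        + u[:, 1:] * (v[tri[:, 2]] - v[tri[:, 0]])
    )
    centroid = pts.mean(axis=0)
    dirs = pts - centroid
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    hull = ConvexHull(dirs)
    faces = hull.simplices.astype(np.int64)
    # orient every face outward from the centroid
    fc = pts[faces].mean(axis=1)
    normals = np.cross(
        pts[faces[:, 1]] - pts[faces[:, 0]], pts[faces[:, 2]] - pts[faces[:, 0]]
    )
    flip = np.einsum("ij,ij->i", normals, fc - centroid) < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return pts, TriSurface(pts, faces)
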