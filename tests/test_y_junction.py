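"""Bifurcation ridge, scaffold, ring projection and conduit meshing."""
from __future__ import annotations

import numpy as np
import pytest

from lvmorph import y_junction as yj
from lvmorph.mesh_core import border_loops_indices
from lvmorph.synthetic import make_bifurcation_target

from conftest import icosphere

DOME_R = 20.0
TUBE_R = 6.0


@pytest.fixture(scope="module")
def target():
    surf, lm = make_bifurcation_target()
    landmarks = yj.JunctionLandmarks(
        lm["saddle_points"], lm["valve_centroids"], lm["vertical_dir"]
    )
    return surf, lm, landmarks


@pytest.fixture(scope="module")
def scaffold(target):
    surf, lm, landmarks = target
    ridge = yj.build_ridge(landmarks, surf)
    scaf = yj.build_scaffold(landmarks, ridge, surf, N=3, k_ridge=5, k_semi=9)
    return ridge, scaf


def union_sdf(p, lm):
    """Analytic signed distance of the dome-plus-tubes union (oracle)."""
    p = np.atleast_2d(p)
    sphere = np.linalg.norm(p, axis=1) - DOME_R
    out = sphere
    for dx in lm["tube_offsets"]:
        radial = np.hypot(p[:, 0] - dx, p[:, 1]) - TUBE_R
        tube = np.maximum(radial, np.maximum(p[:, 2] - 34.0, 6.0 - p[:, 2]))
        out = np.minimum(out, tube)
    return out


def test_ridge_is_sphere_arc(target):
    """Saddle plane is x = 0; the ridge is a great-circle arc of the dome."""
    surf, lm, landmarks = target
    ridge = yj.build_ridge(landmarks, surf)
    assert np.abs(ridge.points[:, 0]).max() < 1e-9
    r = np.linalg.norm(ridge.points, axis=1)
    assert np.abs(r - DOME_R).max() < 0.2  # marching-cubes faceting
    # trimmed between the saddles, passing over the top (shorter arc)
    assert ridge.points[:, 2].min() > lm["saddle_points"][0][2] - 0.5


def test_ridge_on_sphere_with_vertical_plane():
    sphere = icosphere(10.0, 3)
    lm = yj.JunctionLandmarks(
        saddle_points=[[0.0, -6.0, 8.0], [0.0, 6.0, 8.0]],
        valve_centroids=[[-3.0, 0.0, 12.0], [3.0, 0.0, 12.0]],
        vertical_dir=[0, 0, 1],
    )
    ridge = yj.build_ridge(lm, sphere)
    r = np.linalg.norm(ridge.points, axis=1)
    assert np.abs(r - 10.0).max() < 0.05


def test_coincident_saddles_rejected():
    with pytest.raises(yj.LandmarkError, match="coincide"):
        yj.JunctionLandmarks(
            saddle_points=[[0, 1, 2], [0, 1, 2]],
            valve_centroids=[[0, 0, 0], [1, 1, 1]],
            vertical_dir=[0, 0, 1],
        )


def test_saddle_far_from_surface_rejected(target):
    surf, lm, _ = target
    bad = yj.JunctionLandmarks(
        lm["saddle_points"] + np.array([0, 0, 8.0]),
        lm["valve_centroids"],
        lm["vertical_dir"],
    )
    with pytest.raises(yj.LandmarkError, match="mm from the surface"):
        yj.build_ridge(bad, surf)


def test_scaffold_small_inside_large_outside(target, scaffold):
    """Analytic containment: small rings inside the union, large outside."""
    surf, lm, landmarks = target
    _, scaf = scaffold
    for rs, rl in zip(scaf.rings_small, scaf.rings_large):
        assert np.all(union_sdf(rs.reshape(-1, 3), lm) < 0)
        assert np.all(union_sdf(rl.reshape(-1, 3), lm) > 0)


def test_scaffold_endpoint_rows_independent_of_N(target):
    surf, lm, landmarks = target
    ridge = yj.build_ridge(landmarks, surf)
    s2 = yj.build_scaffold(landmarks, ridge, surf, N=2, k_ridge=5, k_semi=9)
    s8 = yj.build_scaffold(landmarks, ridge, surf, N=8, k_ridge=5, k_semi=9)
    for c in range(2):
        assert np.allclose(s2.rings_small[c][0], s8.rings_small[c][0])
        assert np.allclose(s2.rings_small[c][-1], s8.rings_small[c][-1])


def test_scaffold_valve_ring_centroid(target):
    """The epsilon valve ring is centred on the configured valve centroid."""
    surf, lm, landmarks = target
    ridge = yj.build_ridge(landmarks, surf)
    eps = 1e-4
    scaf = yj.build_scaffold(landmarks, ridge, surf, N=3, epsilon=eps,
                             k_ridge=5, k_semi=9)
    for c in range(2):
        centroid = scaf.rings_small[c][-1].mean(axis=0)
        # conduit_length defaults to the bifurcation->centroid distance
        assert np.linalg.norm(centroid - lm["valve_centroids"][c]) < 0.5 + eps


def test_projected_rings_on_tube_wall(target, scaffold):
    """Conduit rows above the dome sit at the tube radius (ray-cylinder)."""
    surf, lm, landmarks = target
    _, scaf = scaffold
    grid = yj.project_conduit_rings(scaf, surf)
    for c, dx in enumerate(lm["tube_offsets"]):
        g = grid.grids[c]
        for row in range(1, g.shape[0]):
            d_ax = np.hypot(g[row][:, 0] - dx, g[row][:, 1])
            assert np.abs(d_ax - TUBE_R).max() < 0.15  # faceting
        # row ordering monotone along the conduit axis
        z_means = g[:, :, 2].mean(axis=1)
        assert np.all(np.diff(z_means) > 0)


def test_projected_rings_all_on_surface(target, scaffold):
    surf, lm, landmarks = target
    _, scaf = scaffold
    grid = yj.project_conduit_rings(scaf, surf)
    from lvmorph._geom import closest_point_on_surface

    for g in grid.grids:
        d, _ = closest_point_on_surface(
            g.reshape(-1, 3), surf.vertices, surf.triangles
        )
        assert d.max() < 1e-9


def test_mesh_junction_counts_and_borders(target, scaffold):
    surf, lm, landmarks = target
    _, scaf = scaffold
    grid = yj.project_conduit_rings(scaf, surf)
    n_sub = 2
    mesh = yj.mesh_junction(grid, n_sub=n_sub)
    rows, K = grid.n_rows, grid.K
    assert len(mesh.quads) == 2 * ((rows - 1) // 2) * (K // 2) * n_sub**2
    loops = border_loops_indices(mesh)
    assert len(loops) == 3  # two valve openings + shared bifurcation bottom


def test_mesh_junction_vertices_on_cylinder():
    """A grid sampled from an analytic cylinder meshes back onto it."""
    K, rows, radius = 8, 5, 6.0
    phi = 2 * np.pi * np.arange(K) / K
    grids = []
    for dx in (-1e3, 1e3):  # far apart: no accidental welding
        rings = np.array(
            [
                np.column_stack(
                    [dx + radius * np.cos(phi), radius * np.sin(phi),
                     np.full(K, z)]
                )
                for z in np.linspace(0, 10, rows)
            ]
        )
        grids.append(rings)
    mesh = yj.mesh_junction(yj.ConduitCPGrid(grids, n_ridge=5), n_sub=4)
    x = np.where(mesh.vertices[:, 0] > 0, mesh.vertices[:, 0] - 1e3,
                 mesh.vertices[:, 0] + 1e3)
    r = np.hypot(x, mesh.vertices[:, 1])
    # quad-9 approximation of a circle arc spanning 90 degrees
    assert np.abs(r - radius).max() < 0.05 * radius


def test_mesh_junction_translation_equivariance():
    K, rows = 8, 3
    phi = 2 * np.pi * np.arange(K) / K
    base = np.array(
        [
            np.column_stack([6 * np.cos(phi), 6 * np.sin(phi), np.full(K, z)])
            for z in (0.0, 5.0, 10.0)
        ]
    )
    off = np.array([100.0, -3.0, 7.0])
    m1 = yj.mesh_junction(yj.ConduitCPGrid([base, base + 500], 5), n_sub=2)
    m2 = yj.mesh_junction(
        yj.ConduitCPGrid([base + off, base + 500 + off], 5), n_sub=2
    )
    assert np.allclose(m2.vertices, m1.vertices + off, atol=1e-9)
    assert np.array_equal(m1.quads, m2.quads)


def test_mesh_junction_parity_violations():
    K, rows = 8, 4  # even row count: invalid
    phi = 2 * np.pi * np.arange(K) / K
    rings = np.array(
        [
            np.column_stack([6 * np.cos(phi), 6 * np.sin(phi), np.full(K, z)])
            for z in np.linspace(0, 9, rows)
        ]
    )
    with pytest.raises(ValueError, match="odd number of rows"):
        yj.mesh_junction(yj.ConduitCPGrid([rings, rings + 100], 5), n_sub=2)
    odd_k = rings[:3, :7]
    with pytest.raises(ValueError, match="even"):
        yj.mesh_junction(yj.ConduitCPGrid([odd_k, odd_k + 100], 5), n_sub=2)


def test_track_landmarks_identity_and_translation(target):
    surf, lm, landmarks = target
    # use on-surface stand-ins for all four points
    on_surf = yj.JunctionLandmarks(
        lm["saddle_points"],
        lm["saddle_points"] + np.array([[0.05, 0, 0], [-0.05, 0, 0]]),
        lm["vertical_dir"],
    )
    same = yj.track_landmarks(on_surf, surf)
    # analytic saddles sit within one marching-cubes facet of the surface
    assert np.allclose(same.saddle_points, on_surf.saddle_points, atol=0.05)
    from lvmorph.mesh_core import TriSurface

    # nearest-point mapping recovers the offset up to its tangential part,
    # so translate along the (near-normal) local radial direction
    off = np.array([0.0, 0.0, 0.6])
    moved = TriSurface(surf.vertices + off, surf.triangles)
    tracked = yj.track_landmarks(on_surf, moved)
    assert np.allclose(
        tracked.saddle_points, on_surf.saddle_points + off, atol=0.3
    )
    from lvmorph._geom import closest_point_on_surface

    d, _ = closest_point_on_surface(
        tracked.saddle_points, moved.vertices, moved.triangles
    )
    assert d.max() < 1e-9


def test_track_landmarks_shrunk_surface(target):
    surf, lm, landmarks = target
    from lvmorph._geom import closest_point_on_surface
    from lvmorph.mesh_core import TriSurface

    centroid = surf.vertices.mean(axis=0)
    shrunk = TriSurface(
        centroid + 0.8 * (surf.vertices - centroid), surf.triangles
    )
    tracked = yj.track_landmarks(landmarks, shrunk)
    d, _ = closest_point_on_surface(
        tracked.saddle_points, shrunk.vertices, shrunk.triangles
    )
    assert d.max() < 1e-9
    for before, after in zip(landmarks.saddle_points, tracked.saddle_points):
        assert np.linalg.norm(after - centroid) < np.linalg.norm(before - centroid)


def test_track_landmarks_lost(target):
    surf, lm, landmarks = target
    from lvmorph.mesh_core import TriSurface

    far = TriSurface(surf.vertices + np.array([500.0, 0, 0]), surf.triangles)
    with pytest.raises(yj.LandmarkError, match="tracking lost"):
        yj.track_landmarks(landmarks, far)


def test_advected_valve_centroids_stay_interior(target):
    """Displacement-transfer tracking keeps orifice centers off the wall."""
    surf, lm, landmarks = target
    from lvmorph.mesh_core import TriSurface

    shrunk = TriSurface(surf.vertices * 0.94, surf.triangles)
    tracked = yj.track_landmarks(landmarks, shrunk, current_surface=surf)
    assert np.all(union_sdf(tracked.valve_centroids / 0.94, lm) < -2.0)
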