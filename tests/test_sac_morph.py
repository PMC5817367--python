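"""Sac template combinatorics, scale fitting, projection and 4D morphing."""
from __future__ import annotations

import numpy as np
import pytest

from lvmorph import metrics, sac_morph
from lvmorph.mesh_core import closed_volume, extract_borders
from lvmorph.synthetic import half_ellipsoid, make_breathing_sac

from conftest import icosphere


@pytest.fixture(scope="module")
def pose():
    return sac_morph.SacPose(
        apex=[0.0, 0.0, -10.0], axis=[0, 0, 1], base_width=24.0, height=10.0
    )


@pytest.mark.parametrize(
    "m,n,patches,cps",
    [(1, 2, 9, 41), (2, 4, 36, 153), (4, 8, 144, 593), (6, 16, 420, 1705)],
)
def test_template_counts(m, n, patches, cps, pose):
    """The truncated-pyramid family reproduces all four printed count pairs."""
    tpl = sac_morph.build_sac_template(m, n, pose)
    assert tpl.n_patches == patches
    assert tpl.n_cps == cps


@pytest.mark.parametrize("m,n", [(1, 1), (3, 2), (2, 5), (5, 3)])
def test_template_count_formulas(m, n, pose):
    """patches = 4mn + m^2 and unique CPs = 2E + 1 for any layout."""
    tpl = sac_morph.build_sac_template(m, n, pose)
    assert tpl.n_patches == 4 * m * n + m * m
    sides = set()
    for g in tpl.patch_grids:
        for pair in (
            (g[0, 0], g[2, 0]), (g[2, 0], g[2, 2]),
            (g[2, 2], g[0, 2]), (g[0, 2], g[0, 0]),
        ):
            sides.add(tuple(sorted(int(x) for x in pair)))
    assert tpl.n_cps == 2 * len(sides) + 1


def test_template_rejects_bad_dims(pose):
    with pytest.raises(ValueError):
        sac_morph.build_sac_template(0, 2, pose)


def test_template_is_conforming_open_disk(pose):
    """The welded template meshes to one conforming sheet with one border."""
    tpl = sac_morph.build_sac_template(2, 3, pose)
    mesh = sac_morph.morph_sac(tpl, tpl.cps, n_sub=2)
    assert len(extract_borders(mesh)) == 1


def test_fit_scales_brackets_concentric_spheres(pose):
    """Scales bracket the inner and outer sphere radii (analytic check)."""
    frames = [icosphere(10.0, 3), icosphere(6.0, 3)]
    tpl = sac_morph.build_sac_template(1, 2, pose)
    s_in, s_out = sac_morph.fit_scales(tpl, frames, margin=0.05)
    assert s_in < s_out
    c = tpl.centroid
    r_in = np.linalg.norm(c + s_in * (tpl.cps - c), axis=1)
    r_out = np.linalg.norm(c + s_out * (tpl.cps - c), axis=1)
    assert r_in.max() < 6.0  # strictly inside the smaller sphere
    assert r_out.min() > 10.0  # strictly outside the larger sphere


def test_fit_scales_pose_error():
    bad_pose = sac_morph.SacPose(
        apex=[50.0, 0, 0], axis=[0, 0, 1], base_width=5.0, height=5.0
    )
    tpl = sac_morph.build_sac_template(1, 2, bad_pose)
    with pytest.raises(sac_morph.PoseError, match="centroid"):
        sac_morph.fit_scales(tpl, [icosphere(10.0, 2)])


def test_project_cps_lands_on_sphere(pose):
    """Projected CPs lie on the faceted sphere; radius within faceting error."""
    sphere = icosphere(10.0, 4)
    tpl = sac_morph.build_sac_template(2, 4, pose)
    s_in, s_out = sac_morph.fit_scales(tpl, [sphere])
    cps = sac_morph.project_cps(tpl, s_in, s_out, sphere)
    from lvmorph._geom import closest_point_on_surface

    d, _ = closest_point_on_surface(cps, sphere.vertices, sphere.triangles)
    assert d.max() < 1e-9
    r = np.linalg.norm(cps, axis=1)
    # icosphere(4) facet sag: deepest at face centroids, ~1.1e-2 mm
    assert np.abs(r - 10.0).max() < 0.02


def test_project_cps_ellipsoid_implicit_residual():
    frames, _ = make_breathing_sac(n_frames=3, noise_sigma=0.0)
    surf = frames[0]
    a, b, c = 25.0, 22.0, 45.0
    pose = sac_morph.SacPose(
        apex=[0, 0, -c], axis=[0, 0, 1], base_width=62.0, height=c
    )
    tpl = sac_morph.build_sac_template(2, 4, pose)
    s_in, s_out = sac_morph.fit_scales(tpl, [surf])
    cps = sac_morph.project_cps(tpl, s_in, s_out, surf)
    res = (cps[:, 0] / a) ** 2 + (cps[:, 1] / b) ** 2 + (cps[:, 2] / c) ** 2
    assert np.abs(res - 1.0).max() < 0.02  # faceting error of the target


def test_project_cps_fallback_warning_and_quality_error():
    """A narrow template fires rim trajectories out of the open base."""
    frames, truth = make_breathing_sac(n_frames=3, noise_sigma=0.0)
    pose = sac_morph.SacPose(
        apex=[0, 0, -45.0], axis=[0, 0, 1], base_width=0.4 * 45, height=45.0
    )
    tpl = sac_morph.build_sac_template(2, 4, pose)
    s_in, s_out = sac_morph.fit_scales(tpl, frames)
    with pytest.raises(sac_morph.ProjectionQualityError):
        with pytest.warns(UserWarning, match="missed the surface"):
            sac_morph.project_cps(tpl, s_in, s_out, frames[0])
    with pytest.warns(UserWarning, match="missed the surface"):
        cps = sac_morph.project_cps(
            tpl, s_in, s_out, frames[0], max_fallback_fraction=1.0
        )
    assert np.all(np.isfinite(cps))


def test_morph_sac_reproduces_template_planes(pose):
    """With projected CPs = template CPs, all nodes lie on the 5 template
    planes (cap + 4 lateral faces of the truncated pyramid)."""
    tpl = sac_morph.build_sac_template(2, 4, pose)
    mesh = sac_morph.morph_sac(tpl, tpl.cps, n_sub=3)
    normals = []
    u1, u2 = pose.frame_vectors()
    # plane through three CPs of each face, built from the pose analytically
    cap_pts = tpl.cps[np.abs((tpl.cps - pose.apex) @ pose.axis) < 1e-9]
    planes = [(pose.apex, pose.axis)]
    half_bot = 0.5 * pose.cap_fraction * pose.base_width
    half_top = 0.5 * pose.base_width
    for sgn, u in [(1, u1), (-1, u1), (1, u2), (-1, u2)]:
        p0 = pose.apex + sgn * half_bot * u
        p1 = pose.apex + pose.axis * pose.height + sgn * half_top * u
        t_dir = np.cross(np.cross(u, pose.axis), p1 - p0)
        nrm = np.cross(p1 - p0, np.cross(u, pose.axis))
        planes.append((p0, nrm / np.linalg.norm(nrm)))
    d = np.full(len(mesh.vertices), np.inf)
    for p0, nrm in planes:
        d = np.minimum(d, np.abs((mesh.vertices - p0) @ nrm))
    assert d.max() < 1e-9 * max(pose.base_width, pose.height)


def test_morph_sac_corner_nodes_independent_of_subdivision(pose):
    tpl = sac_morph.build_sac_template(1, 2, pose)
    rng = np.random.default_rng(5)
    cps = tpl.cps + 0.3 * rng.standard_normal(tpl.cps.shape)
    m1 = sac_morph.morph_sac(tpl, cps, n_sub=1)
    m4 = sac_morph.morph_sac(tpl, cps, n_sub=4)
    for v in m1.vertices:
        assert np.min(np.linalg.norm(m4.vertices - v, axis=1)) < 1e-9


def test_morph_sac_4d_identical_frames(pose):
    frames = [icosphere(10.0, 3)] * 5
    tpl = sac_morph.build_sac_template(1, 2, pose)
    m4d, _ = sac_morph.morph_sac_4d(
        tpl, frames, n_sub=2, sac_fraction=1.0, base_centroid=np.zeros(3)
    )
    assert len(m4d.frames) == 5
    for f in m4d.frames[1:]:
        assert np.array_equal(f.vertices, m4d.frames[0].vertices)
        assert np.array_equal(f.quads, m4d.frames[0].quads)


def test_morph_sac_4d_breathing_ellipsoid_residual():
    """Mean radial residual below 2% of the radius on the analytic target."""
    frames, truth = make_breathing_sac(n_frames=5, noise_sigma=0.0)
    apex = truth["apex_points"][0]
    pose = sac_morph.SacPose(
        apex=apex, axis=[0, 0, 1],
        base_width=sac_morph.suggest_base_width(frames, apex, [0, 0, 1]),
        height=45.0,
    )
    tpl = sac_morph.build_sac_template(2, 4, pose)
    m4d, info = sac_morph.morph_sac_4d(
        tpl, frames, n_sub=4, sac_fraction=1.0, base_centroid=np.zeros(3)
    )
    mean_radius = np.mean(truth["base_radii"])
    for i, mesh in enumerate(m4d.frames):
        rep = metrics.distance_errors(mesh, frames[i])
        assert rep.per_node.mean() < 0.02 * mean_radius


def test_morph_sac_4d_connectivity_byte_identical():
    frames, truth = make_breathing_sac(n_frames=4, noise_sigma=0.2, seed=3)
    apex = truth["apex_points"][0]
    pose = sac_morph.SacPose(
        apex=apex, axis=[0, 0, 1],
        base_width=sac_morph.suggest_base_width(frames, apex, [0, 0, 1]),
        height=45.0,
    )
    tpl = sac_morph.build_sac_template(2, 4, pose)
    m4d, _ = sac_morph.morph_sac_4d(
        tpl, frames, n_sub=2, sac_fraction=1.0, base_centroid=np.zeros(3)
    )
    blob = m4d.frames[0].quads.tobytes()
    assert all(f.quads.tobytes() == blob for f in m4d.frames[1:])


def test_clip_to_sac_half_axis():
    """sac_fraction = 0.5 keeps only geometry below the mid-axis plane."""
    surf = half_ellipsoid((25.0, 22.0, 45.0))
    apex = np.array([0.0, 0.0, -45.0])
    base = np.zeros(3)
    clipped = sac_morph.clip_to_sac(surf, apex, base, 0.5)
    zmax = clipped.vertices[clipped.triangles].reshape(-1, 3)[:, 2].max()
    facet = 45.0 * np.pi / 2 / 24  # one polar step of the fixture
    assert zmax <= -45.0 * 0.5 + facet


def test_morph_sac_4d_clipped_stays_below_plane():
    frames, truth = make_breathing_sac(n_frames=3, noise_sigma=0.0)
    apex = truth["apex_points"][0]
    # pose the template inside the region shared by ALL frames: its apex
    # must sit above the shallowest (end-systolic) apex, or the template
    # centroid ends up outside the small frames
    apex_pose = np.array([0.0, 0.0, truth["apex_points"][:, 2].max() + 1.0])
    pose = sac_morph.SacPose(
        apex=apex_pose, axis=[0, 0, 1],
        base_width=sac_morph.suggest_base_width(frames, apex, [0, 0, 1]),
        height=-22.5 - apex_pose[2],
    )
    tpl = sac_morph.build_sac_template(2, 4, pose)
    m4d, _ = sac_morph.morph_sac_4d(
        tpl, frames, n_sub=2, sac_fraction=0.5,
        base_centroid=np.zeros(3), apex=apex,
    )
    patch_row = 45.0 * 0.5 / (2 * tpl.n)  # one patch-row tolerance
    for mesh in m4d.frames:
        assert mesh.vertices[:, 2].max() <= -45.0 * 0.5 + patch_row
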