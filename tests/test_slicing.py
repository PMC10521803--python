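import numpy as np
import pytest

from craniometrics import (
    CuttingPlane,
    HeadSpec,
    PlanarContour,
    TriangleMesh,
    apply_transform,
    extract_orthogonal_contours,
    find_max_ofd_slice,
    generate_head,
    intersect_plane,
    register_head,
    resample_contour,
)
from craniometrics.errors import (
    EmptySectionError,
    GeometryError,
    OpenContourError,
    SamplingError,
)
from craniometrics.slicing import axial_plane, coronal_plane, sagittal_plane
from craniometrics.synthetic_heads import (
    _radial_distance,
    icosphere,
    random_rigid_transform,
)

from conftest import ellipse_perimeter, make_circle_contour, make_ellipse_contour


@pytest.fixture(scope="module")
def registered_bullet(bullet_head):
    _, mesh, landmarks, _ = bullet_head
    return register_head(mesh, landmarks).mesh


# ---------------------------------------------------------------------------
# intersect_plane


def test_cutting_plane_normalizes():
    p = CuttingPlane([0, 0, 0], [0, 0, 5.0])
    assert abs(np.linalg.norm(p.normal) - 1.0) < 1e-12


def test_cutting_plane_zero_normal():
    with pytest.raises(GeometryError):
        CuttingPlane([0, 0, 0], [0, 0, 0])


def test_icosphere_great_circle():
    dirs, faces = icosphere(3)
    contour = intersect_plane(TriangleMesh(dirs, faces), axial_plane(0.0))
    assert abs(contour.perimeter() - 2 * np.pi) / (2 * np.pi) < 0.01


def test_ellipsoid_equator_perimeter():
    dirs, faces = icosphere(4)
    verts = dirs * np.array([75.0, 100.0, 90.0])
    contour = intersect_plane(TriangleMesh(verts, faces), axial_plane(0.0))
    oracle = ellipse_perimeter(75.0, 100.0)
    assert abs(contour.perimeter() - oracle) / oracle < 0.005
    # points lie in the plane, ordered counterclockwise
    assert np.abs(contour.points[:, 2]).max() < 1e-6


def test_plane_misses_mesh(default_head):
    _, mesh, _, _ = default_head
    z_top = mesh.vertices[:, 2].max()
    with pytest.raises(EmptySectionError):
        intersect_plane(mesh, axial_plane(2.0 * z_top))


def test_open_contour_detected(default_head):
    _, mesh, _, _ = default_head
    z = 40.0
    d = mesh.vertices[:, 2] - z
    crossing = np.flatnonzero(~((d[mesh.faces] > 0).all(axis=1)
                                | (d[mesh.faces] <= 0).all(axis=1)))
    faces = np.delete(mesh.faces, crossing[0], axis=0)
    with pytest.raises(OpenContourError):
        intersect_plane(TriangleMesh(mesh.vertices, faces), axial_plane(z))


def test_perimeter_rigid_invariance(default_head):
    _, mesh, _, _ = default_head
    base = intersect_plane(mesh, axial_plane(30.0)).perimeter()
    rng = np.random.default_rng(21)
    motion = random_rigid_transform(rng)
    moved = apply_transform(mesh, motion)
    plane = CuttingPlane(motion.apply(np.array([0.0, 0.0, 30.0])),
                         motion.rotation @ np.array([0.0, 0.0, 1.0]))
    rotated = intersect_plane(moved, plane).perimeter()
    assert abs(rotated - base) / base < 1e-6


# ---------------------------------------------------------------------------
# max-OFD slice search


def test_ellipsoid_max_ofd_at_equator(default_head):
    _, mesh, landmarks, _ = default_head
    reg = register_head(mesh, landmarks)
    contour = find_max_ofd_slice(reg.mesh, step=1.0)
    assert abs(contour.metadata["slice_z"]) <= 1.0
    assert len(contour.metadata["search_trace"]) > 10


def brute_force_ofd_z(mesh, step):
    best_z, best_ofd = None, -1.0
    z_top = mesh.vertices[:, 2].max()
    for z in np.arange(0.0, z_top, step):
        try:
            c = intersect_plane(mesh, axial_plane(float(z)))
        except GeometryError:
            continue
        ofd = c.points[:, 1].max() - c.points[:, 1].min()
        if ofd > best_ofd + 1e-12:
            best_ofd, best_z = ofd, float(z)
    return best_z


def test_bullet_head_matches_dense_search(registered_bullet):
    contour = find_max_ofd_slice(registered_bullet, step=1.0)
    z_brute = brute_force_ofd_z(registered_bullet, 0.1)
    assert z_brute > 1.0  # the optimum is genuinely off the reference plane
    assert abs(contour.metadata["slice_z"] - z_brute) <= 1.0


def test_single_candidate_when_step_exceeds_height(default_head):
    _, mesh, landmarks, _ = default_head
    reg = register_head(mesh, landmarks)
    contour = find_max_ofd_slice(reg.mesh, step=500.0)
    assert len(contour.metadata["search_trace"]) == 1
    assert contour.metadata["slice_z"] == 0.0


# ---------------------------------------------------------------------------
# orthogonal contours


def test_sphere_orthogonal_isotropy():
    spec = HeadSpec(length_mm=200.0, width_mm=200.0, height_mm=100.0)
    mesh, landmarks, _ = generate_head(spec)
    reg = register_head(mesh, landmarks)
    axial = find_max_ofd_slice(reg.mesh)
    sagittal, coronal = extract_orthogonal_contours(reg.mesh, axial)
    assert sagittal.plane.orientation_label == "sagittal"
    assert coronal.plane.orientation_label == "coronal"
    assert abs(sagittal.perimeter() - coronal.perimeter()) / sagittal.perimeter() < 0.001


def test_sagittal_matches_analytic_profile(default_head):
    spec, mesh, landmarks, _ = default_head
    reg = register_head(mesh, landmarks)
    axial = find_max_ofd_slice(reg.mesh)
    sagittal, _ = extract_orthogonal_contours(reg.mesh, axial)
    # oracle: radial profile of the analytic surface in the x=0 plane
    th = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    dirs = np.column_stack([np.zeros_like(th), np.cos(th), np.sin(th)])
    r = _radial_distance(spec, dirs)
    pts = r[:, None] * dirs
    oracle = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum()
    assert abs(sagittal.perimeter() - oracle) / oracle < 0.005


def test_orthogonal_planes_pass_through_axial_centroid(registered_bullet):
    axial = find_max_ofd_slice(registered_bullet)
    sagittal, coronal = extract_orthogonal_contours(registered_bullet, axial)
    from craniometrics.slicing import contour_centroid_2d

    cx, cy = contour_centroid_2d(axial)
    assert abs(sagittal.plane.origin[0] - cx) < 1e-9
    assert abs(coronal.plane.origin[1] - cy) < 1e-9


# ---------------------------------------------------------------------------
# resampling


def test_resample_circle_constant_radius():
    sampled = resample_contour(make_circle_contour(80.0), 120)
    assert np.abs(sampled.radii - 80.0).max() < 0.1
    assert sampled.n_samples == 120


def test_resample_ellipse_axis_radii():
    sampled = resample_contour(make_ellipse_contour(75.0, 100.0), 120)
    # angle 0 = +y (semi-axis 100), angle pi/2 = -x direction (semi-axis 75)
    assert abs(sampled.radii[0] - 100.0) < 0.2
    assert abs(sampled.radii[30] - 75.0) < 0.2
    assert abs(sampled.radii[60] - 100.0) < 0.2


def test_resample_reconstructs_perimeter(registered_bullet):
    axial = find_max_ofd_slice(registered_bullet)
    sampled = resample_contour(axial, 120)
    assert abs(sampled.perimeter() - axial.perimeter()) / axial.perimeter() < 0.005


def test_resample_equivariant_one_step():
    contour = make_ellipse_contour(75.0, 100.0)
    sampled = resample_contour(contour, 120)
    step = 2.0 * np.pi / 120.0
    rot = np.array([[np.cos(step), -np.sin(step)], [np.sin(step), np.cos(step)]])
    pts2 = contour.points[:, :2] @ rot.T
    rotated = PlanarContour(np.column_stack([pts2, contour.points[:, 2]]),
                            axial_plane(0.0))
    sampled_rot = resample_contour(rotated, 120)
    assert np.abs(np.roll(sampled.radii, 1) - sampled_rot.radii).max() < 1e-9


def test_resample_rejects_non_star_shaped():
    # C-shaped annular sector: rays through the opening cross 2+ times
    th_out = np.linspace(np.deg2rad(20), np.deg2rad(340), 120)
    th_in = th_out[::-1]
    pts = np.concatenate([
        np.column_stack([80 * np.cos(th_out), 80 * np.sin(th_out)]),
        np.column_stack([60 * np.cos(th_in), 60 * np.sin(th_in)]),
    ])
    contour = PlanarContour(np.column_stack([pts, np.zeros(len(pts))]), axial_plane(0.0))
    with pytest.raises(SamplingError) as err:
        resample_contour(contour, 120)
    assert err.value.angle_rad is None or np.isfinite(err.value.angle_rad)


def test_resample_requires_closed_contour():
    contour = make_circle_contour(80.0)
    contour.closed = False
    with pytest.raises(GeometryError):
        resample_contour(contour, 120)


def test_plane_constructors():
    assert sagittal_plane(5.0).origin[0] == 5.0
    assert coronal_plane(-3.0).origin[1] == -3.0
    assert axial_plane(7.0).origin[2] == 7.0
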