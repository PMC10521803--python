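import warnings

import numpy as np
import pytest

from craniometrics import (
    CephalometricRecord,
    GrowthReference,
    HeadSpec,
    IcvCorrection,
    PlanarContour,
    TriangleMesh,
    apply_transform,
    calibrate_icv_correction,
    cephalic_index,
    cranial_volume_above_plane,
    estimate_icv,
    generate_head,
    generate_reference_table,
    measure_bpd,
    measure_head,
    measure_ofc,
    measure_ofd,
    ofc_icv_proxy_check,
    z_score,
)
from craniometrics.cephalometrics import MeasureConfig, caliper_diameter
from craniometrics.errors import (
    DomainError,
    FitError,
    GeometryError,
    ReferenceLookupError,
    VolumeError,
)
from craniometrics.registration import transform_landmarks
from craniometrics.slicing import axial_plane
from craniometrics.synthetic_heads import GrowthModel, random_rigid_transform, scaled_spec

from conftest import ellipse_perimeter, make_circle_contour, make_ellipse_contour


# ---------------------------------------------------------------------------
# contour measurements


def test_ofd_ellipse():
    contour = make_ellipse_contour(75.0, 100.0)
    assert abs(measure_ofd(contour) - 200.0) < 0.2


def test_ofd_circle():
    assert abs(measure_ofd(make_circle_contour(80.0)) - 160.0) < 0.1


def test_bpd_ellipse():
    assert abs(measure_bpd(make_ellipse_contour(75.0, 100.0)) - 150.0) < 0.2


def test_ofd_matches_brute_force(bullet_head):
    from craniometrics import find_max_ofd_slice, register_head

    _, mesh, landmarks, _ = bullet_head
    reg = register_head(mesh, landmarks)
    contour = find_max_ofd_slice(reg.mesh)
    y = contour.points[:, 1]
    assert abs(measure_ofd(contour) - (y.max() - y.min())) < 0.1


def test_open_contour_rejected():
    contour = make_circle_contour(80.0)
    contour.closed = False
    for fn in (measure_ofd, measure_bpd, measure_ofc):
        with pytest.raises(GeometryError):
            fn(contour)


def test_ofc_square():
    pts = np.array([[50.0, 50, 0], [-50, 50, 0], [-50, -50, 0], [50, -50, 0]])
    contour = PlanarContour(pts, axial_plane(0.0))
    assert measure_ofc(contour) == pytest.approx(400.0)


def test_ofc_ellipse_quadrature():
    contour = make_ellipse_contour(75.0, 100.0, n=2048)
    oracle = ellipse_perimeter(100.0, 75.0)
    assert abs(measure_ofc(contour) - oracle) / oracle < 0.005


def test_ofc_homogeneous_under_scaling():
    contour = make_ellipse_contour(75.0, 100.0)
    doubled = PlanarContour(contour.points * 2.0, axial_plane(0.0))
    assert measure_ofc(doubled) == pytest.approx(2.0 * measure_ofc(contour))


def test_caliper_at_least_axis_extent():
    contour = make_ellipse_contour(75.0, 100.0)
    assert caliper_diameter(contour) >= measure_ofd(contour) - 1e-9


def test_cephalic_index_values():
    assert cephalic_index(75.0, 100.0) == pytest.approx(75.0)
    assert cephalic_index(80.0, 80.0) == pytest.approx(100.0)
    assert cephalic_index(150.0, 200.0) == pytest.approx(75.0)
    with pytest.raises(DomainError):
        cephalic_index(75.0, 0.0)


# ---------------------------------------------------------------------------
# volume


def test_half_ellipsoid_volume():
    spec = HeadSpec(length_mm=200.0, width_mm=150.0, height_mm=90.0)
    mesh, _, _ = generate_head(spec)
    oracle = (2.0 / 3.0) * np.pi * 75.0 * 100.0 * 90.0 / 1000.0  # 1413.7 cc
    vol = estimate_icv(mesh, IcvCorrection(slope=1.0, intercept=0.0))
    assert abs(vol - oracle) / oracle < 0.01


def test_hemisphere_volume():
    spec = HeadSpec(length_mm=200.0, width_mm=200.0, height_mm=100.0)
    mesh, _, _ = generate_head(spec)
    oracle = (2.0 / 3.0) * np.pi * 100.0 ** 3 / 1000.0  # 2094.4 cc
    assert abs(estimate_icv(mesh) - oracle) / oracle < 0.01


def test_correction_slope_halves_volume(default_head):
    _, mesh, _, _ = default_head
    full = estimate_icv(mesh)
    half = estimate_icv(mesh, IcvCorrection(slope=0.5, intercept=0.0))
    assert half == pytest.approx(0.5 * full, rel=1e-12)


def test_volume_requires_closed_surface(default_head):
    _, mesh, _, _ = default_head
    above = np.flatnonzero((mesh.vertices[mesh.faces][:, :, 2] > 20.0).all(axis=1))
    holed = TriangleMesh(mesh.vertices, np.delete(mesh.faces, above[0], axis=0))
    with pytest.raises(VolumeError):
        cranial_volume_above_plane(holed)


def test_negative_corrected_volume_rejected(default_head):
    _, mesh, _, _ = default_head
    with pytest.raises(DomainError):
        estimate_icv(mesh, IcvCorrection(slope=1.0, intercept=-1e6))


def test_correction_validation():
    with pytest.raises(DomainError):
        IcvCorrection(slope=-0.5)


# ---------------------------------------------------------------------------
# calibration


def test_calibration_exact_line():
    raw = np.linspace(900.0, 1500.0, 10)
    corr = calibrate_icv_correction(np.column_stack([raw, 0.9 * raw]))
    assert corr.slope == pytest.approx(0.9, abs=1e-12)
    assert corr.intercept == pytest.approx(0.0, abs=1e-9)
    assert corr.r_squared == pytest.approx(1.0, abs=1e-12)


def test_calibration_noisy_recovery_seed3():
    rng = np.random.default_rng(3)
    raw = rng.uniform(900.0, 1500.0, 25)
    ct = 0.82 * raw + 40.0 + rng.normal(0.0, 20.0, 25)
    corr = calibrate_icv_correction(np.column_stack([raw, ct]))
    assert abs(corr.slope - 0.82) < 0.05
    # r^2 equals the squared Pearson correlation computed independently
    assert corr.r_squared == pytest.approx(np.corrcoef(raw, ct)[0, 1] ** 2, abs=1e-12)
    assert corr.n_pairs == 25


def test_calibration_too_few_pairs():
    with pytest.raises(FitError):
        calibrate_icv_correction([(1000.0, 900.0), (1100.0, 990.0)])


def test_calibration_degenerate():
    with pytest.raises(FitError):
        calibrate_icv_correction([(1000.0, 900.0)] * 5)


# ---------------------------------------------------------------------------
# z-scores


def simple_reference(sex="male"):
    return GrowthReference("ofc", sex, [0.0, 12.0, 24.0],
                           [40.0, 48.0, 50.0], [2.0, 2.0, 2.0])


def test_z_score_at_mean_is_zero():
    ref = simple_reference()
    assert z_score(48.0, 12.0, "male", ref) == pytest.approx(0.0)


def test_z_score_one_sd():
    ref = simple_reference()
    assert z_score(50.0, 12.0, "male", ref) == pytest.approx(1.0)


def test_z_score_interpolated_midway():
    # mean 48 -> 50 between 12 and 24 months; at 18 months mean = 49, sd = 2
    ref = simple_reference()
    assert z_score(51.0, 18.0, "male", ref) == pytest.approx(1.0)


def test_z_score_clamps_out_of_range_with_warning():
    ref = simple_reference()
    with pytest.warns(UserWarning, match="outside reference range"):
        z = z_score(50.0, 60.0, "male", ref)
    assert z == pytest.approx(0.0)


def test_z_score_wrong_sex():
    with pytest.raises(ReferenceLookupError):
        z_score(48.0, 12.0, "female", simple_reference("male"))


def test_z_score_monotone_in_value():
    ref = simple_reference()
    values = np.linspace(40.0, 60.0, 15)
    zs = [z_score(v, 12.0, "male", ref) for v in values]
    assert (np.diff(zs) > 0).all()


def test_reference_requires_increasing_ages():
    with pytest.raises(DomainError):
        GrowthReference("ofc", "male", [0.0, 12.0, 12.0], [40, 48, 50], [2, 2, 2])


def test_reference_csv_roundtrip(tmp_path):
    refs = generate_reference_table(GrowthModel(), [6.0, 24.0, 48.0], "male",
                                    mesh_resolution=2)
    path = tmp_path / "refs.csv"
    refs.to_csv(path)
    from craniometrics import ReferenceSet

    back = ReferenceSet.from_csv(path)
    ref = back.get_ref("ofc", "male")
    assert np.allclose(ref.mean, refs.get_ref("ofc", "male").mean)


# ---------------------------------------------------------------------------
# pipeline


def test_measure_head_canonical_ci(default_head):
    _, mesh, landmarks, _ = default_head
    record = measure_head(mesh, landmarks)
    assert abs(record.cephalic_index - 75.0) < 0.3
    assert abs(record.ofd - 200.0) < 0.2
    assert abs(record.bpd - 150.0) < 0.2


def test_measure_head_rigid_invariance_seed11(default_head):
    _, mesh, landmarks, _ = default_head
    base = measure_head(mesh, landmarks)
    rng = np.random.default_rng(11)
    motion = random_rigid_transform(rng)
    moved = measure_head(apply_transform(mesh, motion),
                         transform_landmarks(landmarks, motion))
    for attr in ("ofd", "bpd", "ofc", "cephalic_index", "icv"):
        assert abs(getattr(base, attr) - getattr(moved, attr)) < 1e-4


def test_measure_head_zero_z_on_reference_match():
    growth = GrowthModel()
    refs = generate_reference_table(growth, [12.0, 24.0, 36.0], "male",
                                    ci_mean=80.0, mesh_resolution=3)
    age = 24.0
    length = growth.length(age, "male")
    spec = HeadSpec(length_mm=length, width_mm=0.80 * length,
                    height_mm=growth.height(age, "male"), mesh_resolution=3)
    mesh, landmarks, _ = generate_head(spec)
    record = measure_head(mesh, landmarks, refs, age_months=age, sex="male")
    for z in (record.z_ofc, record.z_ci, record.z_icv):
        assert abs(z) < 0.01


def test_measure_head_scale_equivariance(default_head):
    spec, mesh, landmarks, _ = default_head
    base = measure_head(mesh, landmarks)
    factor = 1.3
    mesh2, landmarks2, _ = generate_head(scaled_spec(spec, factor))
    scaled = measure_head(mesh2, landmarks2)
    assert scaled.ofd == pytest.approx(base.ofd * factor, rel=1e-6)
    assert scaled.bpd == pytest.approx(base.bpd * factor, rel=1e-6)
    assert scaled.ofc == pytest.approx(base.ofc * factor, rel=1e-6)
    assert scaled.icv == pytest.approx(base.icv * factor ** 3, rel=1e-6)
    assert scaled.cephalic_index == pytest.approx(base.cephalic_index, rel=1e-6)


def test_record_warns_on_inverted_proportions():
    with pytest.warns(UserWarning, match="proportions"):
        CephalometricRecord(ofd=140.0, bpd=150.0, ofc=460.0,
                            cephalic_index=100.0 * 150.0 / 140.0, icv=1200.0)


def test_record_ci_consistency(default_head):
    _, mesh, landmarks, _ = default_head
    record = measure_head(mesh, landmarks)
    assert record.cephalic_index == pytest.approx(
        100.0 * record.bpd / record.ofd, abs=1e-9)


# ---------------------------------------------------------------------------
# OFC <-> ICV proxy


def _record(ofc, icv):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return CephalometricRecord(ofd=ofc / np.pi * 1.2, bpd=ofc / np.pi * 0.9,
                                   ofc=ofc, cephalic_index=75.0, icv=icv)


def test_proxy_check_affine_is_one():
    records = [_record(400.0 + i, 3.0 * (400.0 + i) - 200.0) for i in range(10)]
    assert ofc_icv_proxy_check(records) == pytest.approx(1.0)


def test_proxy_check_null_seed5():
    rng = np.random.default_rng(5)
    records = [_record(o, v) for o, v in zip(rng.normal(450, 20, 200),
                                             rng.normal(1200, 100, 200))]
    assert ofc_icv_proxy_check(records) < 0.05


def test_proxy_check_growth_linked_cohort():
    from craniometrics import CohortSpec, generate_cohort

    cohort = generate_cohort(CohortSpec(group_label="g", n_subjects=20,
                                        mesh_resolution=2, seed=17))
    records = [s.ground_truth for s in cohort]
    assert ofc_icv_proxy_check(records) > 0.8


def test_proxy_check_too_few():
    with pytest.raises(FitError):
        ofc_icv_proxy_check([_record(400.0, 1000.0)] * 2)


def test_whole_vault_bpd_at_least_slice_bpd(bullet_head):
    _, mesh, landmarks, _ = bullet_head
    base = measure_head(mesh, landmarks)
    wide = measure_head(mesh, landmarks, config=MeasureConfig(bpd_whole_vault=True))
    assert wide.bpd >= base.bpd - 1e-9
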