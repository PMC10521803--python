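"""Watertight synthetic head surfaces with analytic ground truth.

The generator produces star-shaped (radial) surfaces: a half-ellipsoid vault
above the landmark plane fused to a shallow ellipsoidal cap below it, with
optional Gaussian-profile frontal-bossing and occipital-bullet bumps, a
vertex-flattening factor, seeded radial vertex noise and an optional rigid
perturbation.  Because the surface is an explicit radial function of
direction, every measurement has an independent analytic oracle: slice
contours are recovered by bisection along meridians and the enclosed volume
by spherical quadrature — no mesh is involved in the ground truth.

Also provides cohort generation (age/sex growth model shared across
subjects) and synthetic growth-reference tables for z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .errors import GenerationError, SchemaError
from .mesh_io import LandmarkSet, TriangleMesh
from .registration import RigidTransform
from .cephalometrics import CephalometricRecord, GrowthReference, ReferenceSet

# fixed morphology constants (radians); amplitudes come from HeadSpec
_FRONTAL_DIR = np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0)   # anterior-superior
_BULLET_ELEVATION = np.deg2rad(20.0)                       # above the plane
_BULLET_DIR = np.array([0.0, -np.cos(_BULLET_ELEVATION), np.sin(_BULLET_ELEVATION)])
_FRONTAL_SIGMA = 0.50
_BULLET_SIGMA = 0.45
_FLATTEN_SIGMA = 0.45
_CAP_DEPTH_FRAC = 0.30  # lower-cap depth as a fraction of vault height


@dataclass
class HeadSpec:
    """Parameters of one synthetic head (mm, months)."""

    length_mm: float = 200.0
    width_mm: float = 150.0
    height_mm: float = 100.0
    frontal_bossing: float = 0.0
    occipital_bullet: float = 0.0
    vertex_flattening: float = 0.0
    noise_sd_mm: float = 0.0
    rigid_perturbation: RigidTransform | None = None
    mesh_resolution: int = 4
    seed: int = 0

    def __post_init__(self):
        if min(self.length_mm, self.width_mm, self.height_mm) <= 0:
            raise SchemaError("head axes must be positive")
        if self.frontal_bossing < 0 or self.occipital_bullet < 0:
            raise SchemaError("bump amplitudes must be nonnegative")
        if not (0.0 <= self.vertex_flattening < 1.0):
            raise SchemaError("vertex_flattening must lie in [0, 1)")
        if self.noise_sd_mm < 0:
            raise SchemaError("noise_sd_mm must be nonnegative")


# ---------------------------------------------------------------------------
# radial surface model


def _radial_distance(spec: HeadSpec, dirs: np.ndarray) -> np.ndarray:
    """Analytic radial distance r(u) of the noise-free surface (mm)."""
    dirs = np.asarray(dirs, float).reshape(-1, 3)
    a = spec.width_mm / 2.0
    b = spec.length_mm / 2.0
    uz = dirs[:, 2]
    c = np.where(uz >= 0, spec.height_mm, _CAP_DEPTH_FRAC * spec.height_mm)
    inv_r2 = (dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (uz / c) ** 2
    r = 1.0 / np.sqrt(inv_r2)
    if spec.frontal_bossing > 0:
        theta = np.arccos(np.clip(dirs @ _FRONTAL_DIR, -1.0, 1.0))
        r = r + spec.frontal_bossing * np.exp(-(theta ** 2) / (2 * _FRONTAL_SIGMA ** 2))
    if spec.occipital_bullet > 0:
        theta = np.arccos(np.clip(dirs @ _BULLET_DIR, -1.0, 1.0))
        r = r + spec.occipital_bullet * np.exp(-(theta ** 2) / (2 * _BULLET_SIGMA ** 2))
    if spec.vertex_flattening > 0:
        theta_z = np.arccos(np.clip(uz, -1.0, 1.0))
        r = r * (1.0 - spec.vertex_flattening
                 * np.exp(-(theta_z ** 2) / (2 * _FLATTEN_SIGMA ** 2)))
    return r


# ---------------------------------------------------------------------------
# icosphere


def icosphere(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere (vertices on the unit sphere, outward-wound faces)."""
    verts, faces = _icosphere_cached(subdivisions)
    return verts.copy(), faces.copy()


@lru_cache(maxsize=8)
def _icosphere_cached(subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    g = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, g, 0], [1, g, 0], [-1, -g, 0], [1, -g, 0],
        [0, -1, g], [0, 1, g], [0, -1, -g], [0, 1, -g],
        [g, 0, -1], [g, 0, 1], [-g, 0, -1], [-g, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    verts_list = [v for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts_list)
                verts_list.append(m)
            return cache[key]

        new_faces = []
        for t in faces:
            ab = midpoint(t[0], t[1])
            bc = midpoint(t[1], t[2])
            ca = midpoint(t[2], t[0])
            new_faces += [[t[0], ab, ca], [t[1], bc, ab], [t[2], ca, bc], [ab, bc, ca]]
        faces = np.asarray(new_faces, dtype=np.int64)
    return np.asarray(verts_list), faces


# ---------------------------------------------------------------------------
# head generation


def generate_head(spec: HeadSpec) -> tuple[TriangleMesh, LandmarkSet, CephalometricRecord]:
    """Build one synthetic head.

    Returns the (possibly noisy / rigidly perturbed) watertight mesh, the
    landmark set placed analytically on the z = 0 plane, and a ground-truth
    record computed from the analytic surface (pre-noise, pre-perturbation).
    """
    if spec.mesh_resolution < 1:
        raise GenerationError("mesh_resolution must be >= 1 for a watertight head")
    dirs, faces = icosphere(spec.mesh_resolution)
    radii = _radial_distance(spec, dirs)
    if spec.noise_sd_mm > 0:
        rng = np.random.default_rng(spec.seed)
        radii = radii + rng.normal(0.0, spec.noise_sd_mm, len(radii))
        if (radii <= 0).any():
            raise GenerationError("vertex noise collapsed the surface")
    vertices = radii[:, None] * dirs

    lm_dirs = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    lm_r = _radial_distance(spec, lm_dirs)
    nasion, tragus_left, tragus_right = lm_r[:, None] * lm_dirs

    if spec.rigid_perturbation is not None:
        vertices = spec.rigid_perturbation.apply(vertices)
        nasion = spec.rigid_perturbation.apply(nasion)
        tragus_left = spec.rigid_perturbation.apply(tragus_left)
        tragus_right = spec.rigid_perturbation.apply(tragus_right)

    mesh = TriangleMesh(vertices, faces, metadata={
        "generator": "synthetic_heads",
        "length_mm": spec.length_mm, "width_mm": spec.width_mm,
        "height_mm": spec.height_mm, "seed": spec.seed,
    })
    landmarks = LandmarkSet(nasion, tragus_left, tragus_right)
    return mesh, landmarks, ground_truth_record(spec)


# ---------------------------------------------------------------------------
# analytic oracles (mesh-free)


def analytic_slice(spec: HeadSpec, z: float, n_azimuths: int = 720) -> np.ndarray:
    """In-plane (x, y) contour of the analytic surface at height ``z``.

    For each azimuth the polar angle where the surface reaches height z is
    found by bisection along the meridian.
    """
    phi = 2.0 * np.pi * np.arange(n_azimuths) / n_azimuths
    cphi, sphi = np.cos(phi), np.sin(phi)
    if z <= 0:
        if z < 0:
            raise ValueError("analytic_slice only supports the cranial side (z >= 0)")
        dirs = np.column_stack([cphi, sphi, np.zeros_like(phi)])
        rho = _radial_distance(spec, dirs)
        return np.column_stack([rho * cphi, rho * sphi])
    lo = np.full(n_azimuths, 1e-9)
    hi = np.full(n_azimuths, np.pi / 2.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        sin_m, cos_m = np.sin(mid), np.cos(mid)
        dirs = np.column_stack([sin_m * cphi, sin_m * sphi, cos_m])
        height = _radial_distance(spec, dirs) * cos_m
        above = height > z
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    theta = 0.5 * (lo + hi)
    dirs = np.column_stack([np.sin(theta) * cphi, np.sin(theta) * sphi, np.cos(theta)])
    rho = _radial_distance(spec, dirs) * np.sin(theta)
    return np.column_stack([rho * cphi, rho * sphi])


def analytic_max_ofd_slice_z(spec: HeadSpec, coarse_step: float = 2.0,
                             fine_step: float = 0.2) -> float:
    """Height of the axial slice maximizing anteroposterior extent."""
    z_top = analytic_vertex_height(spec)

    def ofd_at(z):
        pts = analytic_slice(spec, z, n_azimuths=180)
        return pts[:, 1].max() - pts[:, 1].min()

    zs = np.arange(0.0, 0.98 * z_top, coarse_step)
    vals = [ofd_at(z) for z in zs]
    z0 = zs[int(np.argmax(vals))]
    zs_fine = np.arange(max(0.0, z0 - coarse_step), z0 + coarse_step, fine_step)
    vals = [ofd_at(z) for z in zs_fine]
    return float(zs_fine[int(np.argmax(vals))])


def analytic_vertex_height(spec: HeadSpec) -> float:
    r = _radial_distance(spec, np.array([[0.0, 0.0, 1.0]]))[0]
    return float(r)


def analytic_volume_above_plane(spec: HeadSpec, n_theta: int = 96,
                                n_phi: int = 192) -> float:
    """Volume (cc) above z = 0 by spherical quadrature of r^3 / 3.

    The enclosed solid is star-shaped about the origin, so the region above
    the plane is exactly the union of radial segments over the upper
    hemisphere of directions.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    cos_t = 0.5 * (nodes + 1.0)          # cos(theta) in (0, 1)
    w_t = 0.5 * weights
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    dirs = np.empty((n_theta * n_phi, 3))
    dirs[:, 0] = np.outer(sin_t, np.cos(phi)).ravel()
    dirs[:, 1] = np.outer(sin_t, np.sin(phi)).ravel()
    dirs[:, 2] = np.repeat(cos_t, n_phi)
    r = _radial_distance(spec, dirs).reshape(n_theta, n_phi)
    integrand = (r ** 3).mean(axis=1) * 2.0 * np.pi / 3.0
    return float((integrand * w_t).sum() / 1000.0)


def ground_truth_record(spec: HeadSpec) -> CephalometricRecord:
    """Measurements of the analytic (pre-noise, unperturbed) surface."""
    z_star = analytic_max_ofd_slice_z(spec)
    # recentre the contour the way registration does (in-plane centroid)
    pts = analytic_slice(spec, z_star, n_azimuths=2048)
    ofd = float(pts[:, 1].max() - pts[:, 1].min())
    bpd = float(pts[:, 0].max() - pts[:, 0].min())
    closed = np.vstack([pts, pts[:1]])
    ofc = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
    return CephalometricRecord(
        ofd=ofd, bpd=bpd, ofc=ofc,
        cephalic_index=100.0 * bpd / ofd,
        icv=analytic_volume_above_plane(spec),
        slice_z=z_star)


# ---------------------------------------------------------------------------
# growth model, cohorts, reference tables


@dataclass
class GrowthModel:
    """Monotone head-size growth: isotropic scale ~ ((age + t0)/(ref + t0))^p."""

    length_ref_mm: float = 195.0   # anteroposterior axis at the reference age
    ref_age_months: float = 24.0
    age_offset_months: float = 40.0
    exponent: float = 1.0 / 3.0
    height_frac: float = 0.55      # vault height / length
    sex_factor_male: float = 1.02

    def scale(self, age_months: float) -> float:
        return float(((age_months + self.age_offset_months)
                      / (self.ref_age_months + self.age_offset_months)) ** self.exponent)

    def _sex_factor(self, sex: str) -> float:
        return self.sex_factor_male if sex == "male" else 1.0

    def length(self, age_months: float, sex: str) -> float:
        return self.length_ref_mm * self.scale(age_months) * self._sex_factor(sex)

    def height(self, age_months: float, sex: str) -> float:
        return self.height_frac * self.length(age_months, sex)


@dataclass
class CohortSpec:
    """Distributional description of a synthetic scan cohort."""

    group_label: str = "cohort"
    n_subjects: int = 10
    age_range_months: tuple[float, float] = (6.0, 72.0)
    ages: tuple | None = None            # explicit ages override the range
    sex_ratio_male: float = 0.5
    ci_mean: float = 78.0
    ci_sd: float = 3.0
    size_sd_frac: float = 0.03           # SD of the multiplicative size factor
    size_z_offset: float = 0.0           # planted offset in size-factor SD units
    bossing_mean: float = 0.0
    bossing_sd: float = 0.0
    bullet_mean: float = 0.0
    bullet_sd: float = 0.0
    flattening_mean: float = 0.0
    flattening_sd: float = 0.0
    noise_sd_mm: float = 0.3
    mesh_resolution: int = 4
    growth: GrowthModel = field(default_factory=GrowthModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise SchemaError("n_subjects must be >= 1")
        for name in ("ci_sd", "size_sd_frac", "bossing_sd", "bullet_sd",
                     "flattening_sd", "noise_sd_mm"):
            if getattr(self, name) < 0:
                raise SchemaError(f"{name} must be nonnegative")
        if not (0.0 <= self.sex_ratio_male <= 1.0):
            raise SchemaError("sex_ratio_male must lie in [0, 1]")


@dataclass
class CohortSubject:
    mesh: TriangleMesh
    landmarks: LandmarkSet
    age_months: float
    sex: str
    ground_truth: CephalometricRecord
    head_spec: HeadSpec


PRESETS: dict[str, dict] = {
    "normocephalic": dict(ci_mean=80.0, ci_sd=2.5),
    "scaphocephalic": dict(ci_mean=68.0, ci_sd=3.0, bossing_mean=6.0, bossing_sd=1.5,
                           bullet_mean=8.0, bullet_sd=2.0,
                           flattening_mean=0.10, flattening_sd=0.03),
    "postop_FBR": dict(ci_mean=75.0, ci_sd=3.5, bossing_mean=2.0, bossing_sd=1.0,
                       flattening_mean=0.06, flattening_sd=0.03),
    "postop_ESC": dict(ci_mean=74.0, ci_sd=3.5, bullet_mean=2.0, bullet_sd=1.0,
                       flattening_mean=0.07, flattening_sd=0.03),
    "postop_SAC": dict(ci_mean=74.5, ci_sd=3.5, bullet_mean=2.5, bullet_sd=1.0,
                       flattening_mean=0.07, flattening_sd=0.03),
}


def preset_cohort(name: str, **overrides) -> CohortSpec:
    if name not in PRESETS:
        raise SchemaError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    params.setdefault("group_label", name)
    return CohortSpec(**params)


def generate_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Draw per-subject head specs from the cohort distributions (seeded) and
    generate every head; sizes grow monotonically with age."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for _ in range(spec.n_subjects):
        if spec.ages is not None:
            age = float(rng.choice(np.asarray(spec.ages, float)))
        else:
            age = float(rng.uniform(*spec.age_range_months))
        sex = "male" if rng.random() < spec.sex_ratio_male else "female"
        size_factor = 1.0 + spec.size_sd_frac * (spec.size_z_offset + rng.standard_normal())
        size_factor = max(size_factor, 0.5)
        ci = rng.normal(spec.ci_mean, spec.ci_sd) if spec.ci_sd > 0 else spec.ci_mean
        ci = float(np.clip(ci, 50.0, 99.0))
        length = spec.growth.length(age, sex) * size_factor
        head = HeadSpec(
            length_mm=length,
            width_mm=ci / 100.0 * length,
            height_mm=spec.growth.height(age, sex) * size_factor,
            frontal_bossing=max(0.0, rng.normal(spec.bossing_mean, spec.bossing_sd)
                                if spec.bossing_sd > 0 else spec.bossing_mean),
            occipital_bullet=max(0.0, rng.normal(spec.bullet_mean, spec.bullet_sd)
                                 if spec.bullet_sd > 0 else spec.bullet_mean),
            vertex_flattening=float(np.clip(
                rng.normal(spec.flattening_mean, spec.flattening_sd)
                if spec.flattening_sd > 0 else spec.flattening_mean, 0.0, 0.9)),
            noise_sd_mm=spec.noise_sd_mm,
            mesh_resolution=spec.mesh_resolution,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        # bumps extend the OFD beyond the base ellipse, so the realized
        # cephalic index drifts below the drawn parameter; calibrate width
        # against the analytic ground truth (skipped for pure ellipsoids)
        if head.frontal_bossing > 0 or head.occipital_bullet > 0:
            for _ in range(2):
                truth_ci = ground_truth_record(head).cephalic_index
                if abs(truth_ci - ci) < 0.1:
                    break
                head = replace(head, width_mm=head.width_mm * ci / truth_ci)
        mesh, landmarks, truth = generate_head(head)
        truth.age_months = age
        truth.sex = sex
        subjects.append(CohortSubject(mesh, landmarks, age, sex, truth, head))
    return subjects


def generate_reference_table(growth: GrowthModel, ages, sex: str,
                             ci_mean: float = 80.0, ci_sd: float = 2.5,
                             size_sd_frac: float = 0.03,
                             mesh_resolution: int = 4) -> ReferenceSet:
    """Synthetic growth-reference tables for OFC, cephalic index and ICV.

    Means are obtained by running the full measurement pipeline on the
    noise-free mean-parameter head at each age (so the table and pipeline
    share any discretization bias); SDs propagate the cohort's
    size/CI scatter (OFC ~ size, ICV ~ size^3).
    """
    from .cephalometrics import measure_head  # deferred: avoids cycle at import

    ages = np.asarray(list(ages), dtype=float)
    if len(ages) == 0 or (np.diff(ages) <= 0).any():
        raise SchemaError("ages must be strictly increasing")
    rows = {m: [] for m in ("ofc", "cephalic_index", "icv")}
    for age in ages:
        length = growth.length(age, sex)
        head = HeadSpec(length_mm=length, width_mm=ci_mean / 100.0 * length,
                        height_mm=growth.height(age, sex),
                        noise_sd_mm=0.0, mesh_resolution=mesh_resolution)
        mesh, landmarks, _ = generate_head(head)
        rec = measure_head(mesh, landmarks)
        rows["ofc"].append((rec.ofc, size_sd_frac * rec.ofc))
        rows["cephalic_index"].append((rec.cephalic_index, ci_sd))
        rows["icv"].append((rec.icv, 3.0 * size_sd_frac * rec.icv))
    refs = ReferenceSet()
    for meas, vals in rows.items():
        mean = np.array([v[0] for v in vals])
        sd = np.array([v[1] for v in vals])
        refs.add(GrowthReference(meas, sex, ages, mean, sd,
                                 source_label="synthetic stand-in"))
    return refs


def random_rigid_transform(rng: np.random.Generator,
                           max_translation_mm: float = 80.0) -> RigidTransform:
    """Uniformly random proper rotation plus a bounded random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return RigidTransform(rot, t)


def scaled_spec(spec: HeadSpec, factor: float) -> HeadSpec:
    """Isotropically scaled copy of a head spec (lengths and bump amplitudes)."""
    return replace(spec,
                   length_mm=spec.length_mm * factor,
                   width_mm=spec.width_mm * factor,
                   height_mm=spec.height_mm * factor,
                   frontal_bossing=spec.frontal_bossing * factor,
                   occipital_bullet=spec.occipital_bullet * factor)
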