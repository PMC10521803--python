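"""Photocephalometric measurements and their age/sex z-scores.

Implements the five measurements extracted from a registered head mesh —
maximum occipitofrontal diameter (OFD), biparietal diameter (BPD),
occipitofrontal circumference (OFC), cephalic index and approximated
intracranial volume (ICV) — the CT-based linear volume correction, the
growth-reference z-scoring, and the single-scan measurement pipeline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import (
    DomainError,
    FitError,
    GeometryError,
    PipelineError,
    ReferenceLookupError,
    VolumeError,
)
from .mesh_io import LandmarkSet, TriangleMesh
from .registration import register_head
from .slicing import (
    DEFAULT_N_SAMPLES,
    DEFAULT_STEP,
    PlanarContour,
    extract_orthogonal_contours,
    find_max_ofd_slice,
    intersect_plane,
    axial_plane,
    resample_contour,
)

log = logging.getLogger(__name__)

MEASUREMENTS = ("ofc", "cephalic_index", "icv")
_PLANE_EPS = 1e-9


# ---------------------------------------------------------------------------
# records and configuration


@dataclass
class CephalometricRecord:
    """All measurements for one scan; z-scores are NaN when no reference or
    age/sex was supplied."""

    ofd: float
    bpd: float
    ofc: float
    cephalic_index: float
    icv: float
    z_ofc: float = float("nan")
    z_ci: float = float("nan")
    z_icv: float = float("nan")
    age_months: float = float("nan")
    sex: str | None = None
    slice_z: float = float("nan")

    def __post_init__(self):
        if np.isfinite(self.ofd) and np.isfinite(self.bpd):
            if not (self.ofd >= self.bpd > 0):
                warnings.warn(
                    f"unexpected head proportions: OFD {self.ofd:.1f} < BPD {self.bpd:.1f}",
                    stacklevel=3)
            if np.isfinite(self.ofc) and self.ofc < 2.0 * (self.ofd + self.bpd) * 0.9 / 2.0:
                # sanity bound on circumference vs ellipse-like lower bound
                warnings.warn("OFC implausibly small versus OFD/BPD", stacklevel=3)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class MeasureConfig:
    slice_step: float = DEFAULT_STEP
    n_samples: int = DEFAULT_N_SAMPLES
    caliper_diameters: bool = False  # rotating-calipers variant of OFD/BPD
    bpd_whole_vault: bool = False    # max width over all axial slices instead
    icv_plane_z: float = 0.0


@dataclass
class IcvCorrection:
    """Linear map raw photogrammetric volume -> CT-calibrated ICV (cc)."""

    slope: float = 1.0
    intercept: float = 0.0
    r_squared: float = float("nan")
    n_pairs: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise DomainError("ICV correction slope must be positive")
        if np.isfinite(self.r_squared) and not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError("r_squared must lie in [0, 1]")

    def apply(self, raw_cc: float) -> float:
        return self.slope * raw_cc + self.intercept


# ---------------------------------------------------------------------------
# contour measurements


def _require_closed(contour: PlanarContour) -> None:
    if not contour.closed:
        raise GeometryError("measurement requires a closed contour")


def measure_ofd(contour: PlanarContour) -> float:
    """Maximum anteroposterior (+y) extent of a closed axial contour, mm."""
    _require_closed(contour)
    y = contour.points[:, 1]
    return float(y.max() - y.min())


def measure_bpd(contour: PlanarContour) -> float:
    """Maximum transverse (+x) extent of a closed axial contour, mm."""
    _require_closed(contour)
    x = contour.points[:, 0]
    return float(x.max() - x.min())


def measure_ofc(contour: PlanarContour) -> float:
    """Contour perimeter including the closing segment, mm."""
    _require_closed(contour)
    return contour.perimeter()


def caliper_diameter(contour: PlanarContour) -> float:
    """Largest pairwise point distance (rotating-calipers style) — sensitivity
    variant of the axis-aligned extents."""
    _require_closed(contour)
    pts = contour.local_points()
    hull = ConvexHull(pts)
    return float(pdist(pts[hull.vertices]).max())


def cephalic_index(bpd: float, ofd: float) -> float:
    """100 * BPD / OFD (percent)."""
    if ofd <= 0:
        raise DomainError("OFD must be positive")
    return 100.0 * bpd / ofd


# ---------------------------------------------------------------------------
# intracranial volume


def cranial_volume_above_plane(mesh: TriangleMesh, plane_z: float = 0.0) -> float:
    """Raw enclosed volume (cc) of the mesh portion above ``z = plane_z``.

    Triangles are clipped to the upper half-space and the volume is summed as
    signed tetrahedra against an apex on the cut plane, which makes the
    planar cap's contribution identically zero.  The clipped shell must be
    closed except along the cut plane, otherwise :class:`VolumeError`.
    """
    verts = mesh.vertices
    d = verts[:, 2] - plane_z
    d = np.where(np.abs(d) < _PLANE_EPS, _PLANE_EPS, d)
    tris: list[np.ndarray] = []
    for face in mesh.faces:
        fd = d[face]
        above = fd > 0
        if not above.any():
            continue
        if above.all():
            tris.append(verts[face])
            continue
        tris.extend(_clip_triangle(verts[face], fd))
    if not tris:
        raise VolumeError("mesh has no surface above the cut plane")
    tri = np.asarray(tris)
    _check_closed_above(tri, plane_z)
    apex = np.array([0.0, 0.0, plane_z])
    a, b, c = tri[:, 0] - apex, tri[:, 1] - apex, tri[:, 2] - apex
    vol_mm3 = abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0))
    return vol_mm3 / 1000.0


def _clip_triangle(tri: np.ndarray, fd: np.ndarray) -> list[np.ndarray]:
    """Clip one triangle to fd > 0, preserving winding (1 or 2 triangles)."""
    out: list[np.ndarray] = []
    poly: list[np.ndarray] = []
    for i in range(3):
        j = (i + 1) % 3
        if fd[i] > 0:
            poly.append(tri[i])
        if (fd[i] > 0) != (fd[j] > 0):
            t = fd[i] / (fd[i] - fd[j])
            poly.append((1 - t) * tri[i] + t * tri[j])
    for k in range(1, len(poly) - 1):
        out.append(np.array([poly[0], poly[k], poly[k + 1]]))
    return out


def _check_closed_above(tri: np.ndarray, plane_z: float, tol: float = 1e-6) -> None:
    """Every boundary edge of the clipped shell must lie on the cut plane."""
    quant = np.round(tri.reshape(-1, 3) / 1e-9).astype(np.int64)
    _, inv = np.unique(quant, axis=0, return_inverse=True)
    fidx = inv.reshape(-1, 3)
    edges = np.sort(np.concatenate(
        [fidx[:, [0, 1]], fidx[:, [1, 2]], fidx[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts != 2]
    if len(boundary):
        pts = tri.reshape(-1, 3)
        lookup = {}
        for p, i in zip(pts, inv):
            lookup.setdefault(int(i), p)
        for e in boundary:
            for vid in e:
                if abs(lookup[int(vid)][2] - plane_z) > tol:
                    raise VolumeError(
                        "clipped surface is not closed above the cut plane "
                        "(mesh not watertight)")


def estimate_icv(mesh: TriangleMesh, correction: IcvCorrection | None = None,
                 plane_z: float = 0.0) -> float:
    """Approximated intracranial volume in cc: raw cranial volume above the
    nasion-tragi plane passed through the linear CT calibration."""
    correction = correction or IcvCorrection()
    raw = cranial_volume_above_plane(mesh, plane_z)
    corrected = correction.apply(raw)
    if corrected <= 0:
        raise DomainError(f"corrected ICV is non-positive ({corrected:.1f} cc)")
    return corrected


def calibrate_icv_correction(pairs) -> IcvCorrection:
    """OLS fit ``ct = slope * raw + intercept`` from (raw_photo_cc, ct_cc)
    calibration pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FitError("pairs must be (n, 2): raw photogrammetric and CT volumes")
    if len(arr) < 3:
        raise FitError("need at least 3 calibration pairs")
    raw, ct = arr[:, 0], arr[:, 1]
    if np.ptp(raw) < 1e-12:
        raise FitError("all raw volumes identical; slope is unidentifiable")
    res = stats.linregress(raw, ct)
    return IcvCorrection(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2), n_pairs=len(arr))


# ---------------------------------------------------------------------------
# growth references and z-scores


@dataclass
class GrowthReference:
    """Sex-specific (age, mean, sd) rows for one measurement."""

    measurement_name: str
    sex: str
    age_months: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        self.age_months = np.asarray(self.age_months, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if len(self.age_months) == 0:
            raise ReferenceLookupError("empty growth-reference table")
        if not (np.diff(self.age_months) > 0).all():
            raise DomainError("reference ages must be strictly increasing")
        if (self.sd <= 0).any():
            raise DomainError("reference SDs must be positive")

    def interpolate(self, age_months: float) -> tuple[float, float]:
        lo, hi = self.age_months[0], self.age_months[-1]
        if age_months < lo or age_months > hi:
            warnings.warn(
                f"age {age_months:.1f} mo outside reference range "
                f"[{lo:.0f}, {hi:.0f}]; clamping", stacklevel=3)
            age_months = min(max(age_months, lo), hi)
        mean = float(np.interp(age_months, self.age_months, self.mean))
        sd = float(np.interp(age_months, self.age_months, self.sd))
        return mean, sd


class ReferenceSet(dict):
    """Mapping (measurement_name, sex) -> GrowthReference."""

    def add(self, ref: GrowthReference) -> None:
        self[(ref.measurement_name, ref.sex)] = ref

    def get_ref(self, measurement: str, sex: str) -> GrowthReference:
        try:
            return self[(measurement, sex)]
        except KeyError:
            raise ReferenceLookupError(
                f"no reference table for {measurement!r} / {sex!r}") from None

    @classmethod
    def from_csv(cls, path) -> "ReferenceSet":
        df = pd.read_csv(path)
        required = {"measurement", "sex", "age_months", "mean", "sd"}
        if not required <= set(df.columns):
            raise ReferenceLookupError(
                f"reference CSV needs columns {sorted(required)}")
        out = cls()
        for (meas, sex), grp in df.groupby(["measurement", "sex"]):
            grp = grp.sort_values("age_months")
            out.add(GrowthReference(meas, sex, grp["age_months"].to_numpy(),
                                    grp["mean"].to_numpy(), grp["sd"].to_numpy(),
                                    source_label=str(path)))
        return out

    def to_csv(self, path) -> None:
        rows = []
        for (meas, sex), ref in sorted(self.items()):
            for a, m, s in zip(ref.age_months, ref.mean, ref.sd):
                rows.append({"measurement": meas, "sex": sex,
                             "age_months": a, "mean": m, "sd": s})
        pd.DataFrame(rows).to_csv(path, index=False)


def z_score(value: float, age_months: float, sex: str,
            reference: GrowthReference) -> float:
    """(value - reference mean) / reference SD with age-linear interpolation."""
    if reference.sex != sex:
        raise ReferenceLookupError(
            f"reference table is for sex {reference.sex!r}, not {sex!r}")
    mean, sd = reference.interpolate(age_months)
    return (value - mean) / sd


# ---------------------------------------------------------------------------
# full pipeline


def measure_head(mesh: TriangleMesh, landmarks: LandmarkSet,
                 references: ReferenceSet | None = None,
                 correction: IcvCorrection | None = None,
                 age_months: float | None = None, sex: str | None = None,
                 config: MeasureConfig | None = None) -> CephalometricRecord:
    """Register, slice, and measure one head scan; deterministic for fixed
    inputs.  Errors are re-raised as :class:`PipelineError` labeled with the
    failing stage."""
    config = config or MeasureConfig()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    registered = _stage("registration", register_head, mesh, landmarks,
                        config.slice_step)
    axial = _stage("ofd-slice-search", find_max_ofd_slice, registered.mesh,
                   config.slice_step)
    _stage("orthogonal-slices", extract_orthogonal_contours, registered.mesh, axial)

    if config.caliper_diameters:
        ofd = _stage("ofd", caliper_diameter, axial)
        bpd_contour = axial
        bpd = measure_bpd(bpd_contour)
    else:
        ofd = _stage("ofd", measure_ofd, axial)
        bpd = _stage("bpd", measure_bpd, axial)
    if config.bpd_whole_vault:
        bpd = _stage("bpd-whole-vault", _max_transverse_width, registered.mesh,
                     config.slice_step)
    ofc = _stage("ofc", measure_ofc, axial)
    ci = _stage("cephalic-index", cephalic_index, bpd, ofd)
    icv = _stage("icv", estimate_icv, registered.mesh, correction,
                 config.icv_plane_z)

    record = CephalometricRecord(
        ofd=ofd, bpd=bpd, ofc=ofc, cephalic_index=ci, icv=icv,
        age_months=float("nan") if age_months is None else float(age_months),
        sex=sex, slice_z=float(axial.metadata.get("slice_z", float("nan"))))
    if references is not None and age_months is not None and sex is not None:
        record.z_ofc = z_score(ofc, age_months, sex, references.get_ref("ofc", sex))
        record.z_ci = z_score(ci, age_months, sex,
                              references.get_ref("cephalic_index", sex))
        record.z_icv = z_score(icv, age_months, sex, references.get_ref("icv", sex))
    log.info("measured head: OFD %.1f BPD %.1f OFC %.1f CI %.1f ICV %.0f",
             record.ofd, record.bpd, record.ofc, record.cephalic_index, record.icv)
    return record


def _max_transverse_width(mesh: TriangleMesh, step: float) -> float:
    best = 0.0
    z_top = float(mesh.vertices[:, 2].max())
    for z in np.arange(0.0, z_top, step):
        try:
            contour = intersect_plane(mesh, axial_plane(float(z)))
        except GeometryError:
            continue
        best = max(best, measure_bpd(contour))
    if best <= 0:
        raise GeometryError("no axial slice found for whole-vault width")
    return best


def ofc_icv_proxy_check(records) -> float:
    """R^2 of the OLS fit icv ~ ofc over a set of records (proxy validity)."""
    ofc = np.array([r.ofc for r in records], dtype=float)
    icv = np.array([r.icv for r in records], dtype=float)
    keep = np.isfinite(ofc) & np.isfinite(icv)
    ofc, icv = ofc[keep], icv[keep]
    if len(ofc) < 3:
        raise FitError("need at least 3 records with finite OFC and ICV")
    if np.ptp(ofc) < 1e-12 or np.ptp(icv) < 1e-12:
        raise FitError("degenerate variance in OFC or ICV")
    res = stats.linregress(ofc, icv)
    return float(res.rvalue ** 2)


def resample_axial(contour: PlanarContour, n_samples: int = DEFAULT_N_SAMPLES):
    """Convenience re-export used by the CLI."""
    return resample_contour(contour, n_samples)
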