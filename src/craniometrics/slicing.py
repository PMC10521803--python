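"""Planar contour extraction from registered head meshes.

Provides the mesh-plane section primitive, the iterative search for the
axial slice with the largest occipitofrontal diameter, the orthogonal
sagittal/coronal slices through that slice's centroid, and the 120-point
angular resampling that gives pointwise correspondence across subjects.

Contour-local 2D frames (abscissa, ordinate):
  axial    (x, y)   — ordinate +y is anterior
  sagittal (y, z)   — ordinate +z is superior
  coronal  (x, z)   — ordinate +z is superior
Resampling angle 0 points along the local ordinate and increases
counterclockwise in the local frame.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .errors import (
    EmptySectionError,
    GeometryError,
    OpenContourError,
    OrientationError,
    SamplingError,
)
from .mesh_io import TriangleMesh

DEFAULT_N_SAMPLES = 120
DEFAULT_STEP = 1.0  # mm

#: signed distances within this of zero are nudged off the plane (mm)
_PLANE_EPS = 1e-9

# local in-plane bases per orientation label: (abscissa axis, ordinate axis)
_LOCAL_BASES = {
    "axial": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])),
    "sagittal": (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    "coronal": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
}


@dataclass
class CuttingPlane:
    origin: np.ndarray
    normal: np.ndarray
    orientation_label: str | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(self.normal)
        if norm < 1e-12:
            raise GeometryError("plane normal has zero length")
        self.normal = self.normal / norm

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane (abscissa, ordinate) unit vectors."""
        if self.orientation_label in _LOCAL_BASES:
            return _LOCAL_BASES[self.orientation_label]
        # arbitrary plane: any orthonormal pair completing the normal
        a = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(a, self.normal)) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = a - np.dot(a, self.normal) * self.normal
        u /= np.linalg.norm(u)
        return u, np.cross(self.normal, u)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        rel = np.asarray(points, float) - self.origin
        return np.column_stack([rel @ u, rel @ v])

    def to_world(self, points2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        points2d = np.asarray(points2d, float)
        return self.origin + np.outer(points2d[:, 0], u) + np.outer(points2d[:, 1], v)


def axial_plane(z: float) -> CuttingPlane:
    return CuttingPlane(np.array([0.0, 0.0, z]), np.array([0.0, 0.0, 1.0]), "axial")


def sagittal_plane(x: float) -> CuttingPlane:
    return CuttingPlane(np.array([x, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), "sagittal")


def coronal_plane(y: float) -> CuttingPlane:
    return CuttingPlane(np.array([0.0, y, 0.0]), np.array([0.0, 1.0, 0.0]), "coronal")


@dataclass
class PlanarContour:
    """Closed cross-section polyline; points lie in ``plane`` and the closing
    segment (last -> first) is implicit."""

    points: np.ndarray
    plane: CuttingPlane
    closed: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)

    def local_points(self) -> np.ndarray:
        return self.plane.to_local(self.points)

    def perimeter(self) -> float:
        pts = self.points
        seg = np.diff(pts, axis=0)
        total = float(np.linalg.norm(seg, axis=1).sum())
        if self.closed:
            total += float(np.linalg.norm(pts[0] - pts[-1]))
        return total

    def is_simple(self) -> bool:
        return bool(Polygon(self.local_points()).is_valid)


@dataclass
class SampledContour:
    """Angular resampling of a closed contour to exactly ``n_samples`` points.

    ``points`` are absolute 2D positions in the contour-local frame; point k
    lies on the ray from ``center`` at angle ``2*pi*k/n_samples``
    counterclockwise from ``start_direction``.
    """

    points: np.ndarray
    n_samples: int
    center: np.ndarray
    start_direction: np.ndarray
    orientation_label: str | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        self.center = np.asarray(self.center, dtype=np.float64).reshape(2)
        self.start_direction = np.asarray(self.start_direction, dtype=np.float64).reshape(2)
        if len(self.points) != self.n_samples:
            raise GeometryError("sampled contour point count != n_samples")

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.points - self.center, axis=1)

    @property
    def angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_samples) / self.n_samples

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# mesh-plane section


def intersect_plane(mesh: TriangleMesh, plane: CuttingPlane) -> PlanarContour:
    """Section a mesh with a plane and return the largest closed loop.

    Crossing triangles each contribute one segment whose endpoints lie on
    mesh edges; segments are chained via shared edges into loops.  The
    largest-perimeter loop is returned, ordered counterclockwise in the
    plane's local frame.  Raises :class:`EmptySectionError` when the plane
    misses the mesh and :class:`OpenContourError` when only open chains
    exist (mesh not watertight where it is cut).
    """
    d = (mesh.vertices - plane.origin) @ plane.normal
    d = np.where(np.abs(d) < _PLANE_EPS, _PLANE_EPS, d)  # nudge on-plane vertices
    fd = d[mesh.faces]  # (m, 3) signed distances per face corner
    pos = fd > 0
    crossing = ~(pos.all(axis=1) | (~pos).all(axis=1))
    if not crossing.any():
        raise EmptySectionError("plane does not intersect the mesh")

    faces = mesh.faces[crossing]
    fdist = fd[crossing]
    edge_pairs = ((0, 1), (1, 2), (2, 0))
    # per crossing face, the two edges whose endpoints straddle the plane
    seg_edges = []  # list of (edge_key_a, edge_key_b) per face
    point_of_edge: dict[tuple[int, int], np.ndarray] = {}
    for face, dist in zip(faces, fdist):
        keys = []
        for a, b in edge_pairs:
            if (dist[a] > 0) != (dist[b] > 0):
                ia, ib = int(face[a]), int(face[b])
                key = (ia, ib) if ia < ib else (ib, ia)
                if key not in point_of_edge:
                    t = dist[a] / (dist[a] - dist[b])
                    point_of_edge[key] = (1 - t) * mesh.vertices[ia] + t * mesh.vertices[ib]
                keys.append(key)
        if len(keys) == 2:
            seg_edges.append((keys[0], keys[1]))

    # adjacency: edge key -> neighbouring edge keys through segments
    neighbours: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for ka, kb in seg_edges:
        neighbours.setdefault(ka, []).append(kb)
        neighbours.setdefault(kb, []).append(ka)

    loops: list[list[tuple[int, int]]] = []
    open_chain_seen = False
    visited: set[tuple[int, int]] = set()
    for start in neighbours:
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        prev = None
        node = start
        closed = False
        while True:
            nxt = [k for k in neighbours[node] if k != prev]
            if not nxt:
                break
            step = nxt[0]
            if step == start:
                closed = True
                break
            if step in visited:
                break
            chain.append(step)
            visited.add(step)
            prev, node = node, step
        if closed and len(chain) >= 3:
            loops.append(chain)
        else:
            open_chain_seen = True

    if not loops:
        if open_chain_seen:
            raise OpenContourError("plane section produced only open chains")
        raise EmptySectionError("plane does not intersect the mesh")

    best_pts, best_perim = None, -1.0
    for chain in loops:
        pts = np.array([point_of_edge[k] for k in chain])
        closed_pts = np.vstack([pts, pts[:1]])
        perim = float(np.linalg.norm(np.diff(closed_pts, axis=0), axis=1).sum())
        if perim > best_perim:
            best_perim, best_pts = perim, pts

    # drop near-duplicate consecutive points (plane passing through vertices)
    closed_pts = np.vstack([best_pts, best_pts[:1]])
    keep = np.linalg.norm(np.diff(closed_pts, axis=0), axis=1) > 1e-9
    best_pts = best_pts[keep]
    # orient counterclockwise in the plane's local frame
    local = plane.to_local(best_pts)
    area = _shoelace(local)
    if area < 0:
        best_pts = best_pts[::-1]
    if len(best_pts) < 8:
        raise GeometryError(f"section loop has only {len(best_pts)} points")
    return PlanarContour(points=best_pts, plane=plane, closed=True)


def _shoelace(pts2d: np.ndarray) -> float:
    x, y = pts2d[:, 0], pts2d[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def contour_centroid_2d(contour: PlanarContour) -> tuple[float, float]:
    """Area centroid of the closed contour in its local frame."""
    poly = Polygon(contour.local_points())
    if not poly.is_valid or poly.area <= 0:
        # fall back to vertex mean for degenerate polygons
        c = contour.local_points().mean(axis=0)
        return float(c[0]), float(c[1])
    c = poly.centroid
    return float(c.x), float(c.y)


# ---------------------------------------------------------------------------
# slice searches


def _contour_extent(contour: PlanarContour, axis: int) -> float:
    vals = contour.points[:, axis]
    return float(vals.max() - vals.min())


def find_max_ofd_slice(mesh: TriangleMesh, step: float = DEFAULT_STEP,
                       z_min: float = 0.0, z_max: float | None = None) -> PlanarContour:
    """Scan axial planes from ``z_min`` to ``z_max`` in steps of ``step`` and
    return the contour with the largest occipitofrontal diameter
    (anteroposterior extent).  Ties go to the inferior slice; the search
    trace is stored in ``contour.metadata['search_trace']`` as (z, OFD)
    pairs."""
    if step <= 0:
        raise ValueError("step must be positive")
    if z_max is None:
        z_max = float(mesh.vertices[:, 2].max())
    trace = []
    best = None  # (ofd, z, contour)
    for z in np.arange(z_min, z_max + 0.5 * step, step):
        try:
            contour = intersect_plane(mesh, axial_plane(float(z)))
        except GeometryError:  # missed, open, or degenerate near-apex section
            continue
        ofd = _contour_extent(contour, axis=1)
        trace.append((float(z), ofd))
        if best is None or ofd > best[0] + 1e-12:
            best = (ofd, float(z), contour)
    if best is None:
        raise OrientationError("no axial plane in the search range intersects the mesh")
    best[2].metadata["search_trace"] = trace
    best[2].metadata["slice_z"] = best[1]
    return best[2]


def extract_orthogonal_contours(mesh: TriangleMesh,
                                axial: PlanarContour) -> tuple[PlanarContour, PlanarContour]:
    """Sagittal and coronal contours through the axial contour's centroid."""
    cx, cy = contour_centroid_2d(axial)
    sagittal = intersect_plane(mesh, sagittal_plane(cx))
    coronal = intersect_plane(mesh, coronal_plane(cy))
    return sagittal, coronal


# ---------------------------------------------------------------------------
# angular resampling


def resample_contour(contour: PlanarContour,
                     n_samples: int = DEFAULT_N_SAMPLES) -> SampledContour:
    """Resample a closed star-shaped contour at ``n_samples`` equally spaced
    angles about its area centroid.

    Sample k is the exact intersection of the polyline with the ray at angle
    ``2*pi*k/n_samples`` counterclockwise from the local ordinate (anterior
    for axial, superior for sagittal/coronal), which pins index
    correspondence across subjects.  Raises :class:`SamplingError` (with the
    offending angle) when the contour is not star-shaped about its centroid.
    """
    if not contour.closed:
        raise GeometryError("can only resample closed contours")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    local = contour.local_points()
    center = np.array(contour_centroid_2d(contour))
    rel = local - center

    radii = np.linalg.norm(rel, axis=1)
    if (radii < 1e-9).any():
        raise SamplingError("contour passes through its centroid")
    # angle from the +ordinate axis, counterclockwise
    ang = np.arctan2(-rel[:, 0], rel[:, 1])
    unwrapped = np.unwrap(ang)
    total = unwrapped[-1] - unwrapped[0] + _closing_turn(ang[-1], ang[0])
    if total < 0:  # clockwise polyline: flip to counterclockwise
        rel = rel[::-1]
        radii = radii[::-1]
        ang = ang[::-1]
        unwrapped = np.unwrap(ang)
        total = unwrapped[-1] - unwrapped[0] + _closing_turn(ang[-1], ang[0])
    if abs(total - 2.0 * np.pi) > 1e-6:
        raise SamplingError(
            f"contour winds {total:.4f} rad about its centroid (not a single loop)")
    steps = np.diff(unwrapped)
    if (steps < -1e-9).any():
        bad = int(np.argmax(steps < -1e-9))
        raise SamplingError(
            "contour is not star-shaped about its centroid "
            f"(angle reversal near {np.mod(unwrapped[bad], 2 * np.pi):.4f} rad)",
            angle_rad=float(np.mod(unwrapped[bad], 2 * np.pi)))

    # wrap the polyline so segment angles cover [theta0, theta0 + 2*pi]
    verts = np.vstack([rel, rel[:1]])
    vang = np.concatenate([unwrapped, [unwrapped[0] + 2.0 * np.pi]])

    targets = 2.0 * np.pi * np.arange(n_samples) / n_samples
    # lift each target angle into [vang[0], vang[0] + 2*pi)
    lifted = vang[0] + np.mod(targets - vang[0], 2.0 * np.pi)
    seg = np.searchsorted(vang, lifted, side="right") - 1
    seg = np.clip(seg, 0, len(vang) - 2)

    p0 = verts[seg]
    p1 = verts[seg + 1]
    # direction of angle t measured from +ordinate, counterclockwise: (-sin t, cos t)
    dirs = np.column_stack([-np.sin(lifted), np.cos(lifted)])
    cross_d_p0 = dirs[:, 0] * p0[:, 1] - dirs[:, 1] * p0[:, 0]
    cross_d_dp = dirs[:, 0] * (p1 - p0)[:, 1] - dirs[:, 1] * (p1 - p0)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.abs(cross_d_dp) > 1e-15, -cross_d_p0 / cross_d_dp, 0.0)
    s = np.clip(s, 0.0, 1.0)
    hit = p0 + s[:, None] * (p1 - p0)
    r = np.einsum("ij,ij->i", hit, dirs)
    points = center + r[:, None] * dirs
    return SampledContour(points=points, n_samples=n_samples, center=center,
                          start_direction=np.array([0.0, 1.0]),
                          orientation_label=contour.plane.orientation_label)


def _closing_turn(a_last: float, a_first: float) -> float:
    """Signed turn of the implicit closing segment, in (-pi, pi]."""
    return float(np.mod(a_first - a_last + np.pi, 2.0 * np.pi) - np.pi)


# ---------------------------------------------------------------------------
# serialization


def sampled_contour_to_csv(sampled: SampledContour, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["angle_deg", "radius_mm", "x_mm", "y_mm"])
        for ang, r, p in zip(np.degrees(sampled.angles), sampled.radii, sampled.points):
            writer.writerow([f"{ang:.6f}", f"{r:.6f}", f"{p[0]:.6f}", f"{p[1]:.6f}"])


def contour_to_json(contour: PlanarContour, path) -> None:
    payload = {
        "orientation": contour.plane.orientation_label,
        "plane": {"origin": [float(x) for x in contour.plane.origin],
                  "normal": [float(x) for x in contour.plane.normal]},
        "closed": contour.closed,
        "points": [[float(c) for c in p] for p in contour.points],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
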