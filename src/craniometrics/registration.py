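"""Rigid registration of head meshes to the nasion-tragi anatomical frame.

Canonical frame: the nasion-tragi plane is z = 0 with the cranial vertex on
+z, tragus_left -> tragus_right is +x, and the nasion lies on the +y
half-axis.  After the landmark alignment the head is re-anchored so that the
centroid of the largest-circumference axial slice sits at x = y = 0 (z is
left unchanged).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, OrientationError
from .mesh_io import LandmarkSet, TriangleMesh

log = logging.getLogger(__name__)

_ORTHO_TOL = 1e-9
_LANDMARK_SURFACE_WARN_MM = 15.0

DEFAULT_SLICE_STEP = 1.0  # mm


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise GeometryError(f"rotation not orthonormal (max deviation {err:.2e})")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise GeometryError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_dict(self) -> dict:
        return {"rotation": [float(x) for x in self.rotation.ravel()],
                "translation": [float(x) for x in self.translation]}

    @classmethod
    def from_dict(cls, data: dict) -> "RigidTransform":
        return cls(np.asarray(data["rotation"], float).reshape(3, 3),
                   np.asarray(data["translation"], float))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RegisteredHead:
    """A head mesh and its landmarks in the canonical anatomical frame."""

    mesh: TriangleMesh
    landmarks: LandmarkSet
    transform: RigidTransform  # source -> canonical
    anchor: np.ndarray = field(default_factory=lambda: np.zeros(3))


def build_landmark_frame(landmarks: LandmarkSet) -> RigidTransform:
    """Closed-form transform mapping the landmarks into the canonical frame.

    The landmark centroid goes to the origin, the nasion-tragi plane to
    z = 0 (vertex side +z), tragus_left->tragus_right to +x and the nasion
    onto the +y half-axis.  Handedness is resolved by the landmark labels,
    so the result is always a proper rotation.
    """
    centroid = landmarks.centroid
    x_axis = landmarks.tragus_right - landmarks.tragus_left
    nx = np.linalg.norm(x_axis)
    if nx < 1e-12:
        raise GeometryError("tragi coincide")
    x_axis = x_axis / nx
    y_raw = landmarks.nasion - centroid
    y_axis = y_raw - np.dot(y_raw, x_axis) * x_axis
    ny = np.linalg.norm(y_axis)
    if ny < 1e-9:
        raise GeometryError("landmarks are collinear")
    y_axis = y_axis / ny
    z_axis = np.cross(x_axis, y_axis)
    rotation = np.vstack([x_axis, y_axis, z_axis])
    return RigidTransform(rotation, -rotation @ centroid)


def apply_transform(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Map every vertex by the rigid motion; faces are unchanged."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy(), dict(mesh.metadata))


def transform_landmarks(landmarks: LandmarkSet, transform: RigidTransform) -> LandmarkSet:
    return LandmarkSet(*(transform.apply(getattr(landmarks, n))
                         for n in ("nasion", "tragus_left", "tragus_right")))


def register_head(mesh: TriangleMesh, landmarks: LandmarkSet,
                  slice_step: float = DEFAULT_SLICE_STEP) -> RegisteredHead:
    """Align a head to the canonical frame and re-anchor it in-plane.

    After the landmark alignment, axial planes parallel to z = 0 are scanned
    upward in steps of ``slice_step`` and the in-plane translation that moves
    the centroid of the largest-circumference (max perimeter) slice to
    x = y = 0 is applied; z is not changed.  Ties in perimeter go to the
    inferior slice.
    """
    from .slicing import axial_plane, contour_centroid_2d, intersect_plane

    if slice_step <= 0:
        raise ValueError("slice_step must be positive")
    frame = build_landmark_frame(landmarks)
    aligned = apply_transform(mesh, frame)
    aligned_lm = transform_landmarks(landmarks, frame)

    # advisory: landmarks should sit on or near the scanned surface
    for name in ("nasion", "tragus_left", "tragus_right"):
        p = getattr(aligned_lm, name)
        dist = float(np.min(np.linalg.norm(aligned.vertices - p, axis=1)))
        if dist > _LANDMARK_SURFACE_WARN_MM:
            warnings.warn(
                f"landmark {name!r} is {dist:.1f} mm from the mesh surface",
                stacklevel=2)

    z_max = float(aligned.vertices[:, 2].max())
    if z_max <= 0:
        raise OrientationError("mesh lies entirely below the nasion-tragi plane")
    best = None  # (perimeter, z, contour)
    for z in np.arange(0.0, z_max, slice_step):
        try:
            contour = intersect_plane(aligned, axial_plane(z))
        except GeometryError:
            continue
        perim = contour.perimeter()
        if best is None or perim > best[0] + 1e-12:
            best = (perim, z, contour)
    if best is None:
        raise OrientationError("no axial slice found on the cranial side")
    cx, cy = contour_centroid_2d(best[2])
    inplane = RigidTransform(np.eye(3), np.array([-cx, -cy, 0.0]))
    total = inplane.compose(frame)
    registered_mesh = apply_transform(mesh, total)
    registered_mesh.metadata["max_circumference_slice_z"] = float(best[1])
    registered_lm = transform_landmarks(landmarks, total)
    log.info("registered head: max-circumference slice at z=%.2f mm, perimeter %.1f mm",
             best[1], best[0])
    return RegisteredHead(mesh=registered_mesh, landmarks=registered_lm,
                          transform=total, anchor=landmarks.centroid)
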