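"""Triangle-mesh and landmark file I/O plus geometry validation.

Meshes are stored in millimeters.  Supported formats: OBJ (ascii), PLY
(ascii and binary little-endian) and STL (ascii and binary).  Landmarks are
a JSON object with keys ``nasion``, ``tragus_left``, ``tragus_right`` or a
CSV with columns ``name,x,y,z``.
"""

from __future__ import annotations

import csv
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import GeometryError, InputError, SchemaError

log = logging.getLogger(__name__)

#: duplicate-vertex merge tolerance (mm); STL stores vertices per-facet
MERGE_TOL = 1e-6

#: plausible head bounding-box extent range in mm
_UNIT_RANGE = (120.0, 400.0)

#: degenerate-face area threshold (mm^2)
_DEGENERATE_AREA = 1e-10

_COLLINEAR_AREA_TOL = 1e-6

LANDMARK_NAMES = ("nasion", "tragus_left", "tragus_right")


@dataclass
class TriangleMesh:
    """Triangle surface mesh in millimeters.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    metadata : free-form dict (source path, subject id, age, sex, ...)
    """

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        self.faces = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (m, 3) array")
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise GeometryError("face index out of range")
        if not np.isfinite(self.vertices).all():
            raise GeometryError("non-finite vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] vertex coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), dict(self.metadata))

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def edges(self) -> np.ndarray:
        """All undirected face edges as sorted index pairs, (3m, 2)."""
        e = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.sort(e, axis=1)

    def is_watertight(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if not len(self.faces):
            return False
        _, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return bool((counts == 2).all())

    def n_components(self) -> int:
        """Number of vertex-connected components among referenced vertices."""
        if not len(self.faces):
            return 0
        e = self.edges()
        n = self.n_vertices
        adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        n_comp, labels = connected_components(adj, directed=False)
        referenced = np.zeros(n, dtype=bool)
        referenced[self.faces.ravel()] = True
        return int(len(np.unique(labels[referenced])))

    def signed_volume(self) -> float:
        """Signed enclosed volume (mm^3); meaningful for closed surfaces."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


@dataclass
class LandmarkSet:
    """Nasion and both tragi (mm); they define the anatomical reference plane."""

    nasion: np.ndarray
    tragus_left: np.ndarray
    tragus_right: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            if not np.isfinite(p).all():
                raise GeometryError(f"non-finite coordinates for landmark {name!r}")
            setattr(self, name, p)
        if self.triangle_area() <= _COLLINEAR_AREA_TOL:
            raise GeometryError("landmarks are collinear (triangle area below tolerance)")

    def triangle_area(self) -> float:
        return 0.5 * float(np.linalg.norm(
            np.cross(self.tragus_right - self.tragus_left, self.nasion - self.tragus_left)))

    def as_array(self) -> np.ndarray:
        """(3, 3) array ordered nasion, tragus_left, tragus_right."""
        return np.vstack([self.nasion, self.tragus_left, self.tragus_right])

    @property
    def centroid(self) -> np.ndarray:
        return self.as_array().mean(axis=0)


@dataclass
class ValidationReport:
    watertight: bool
    n_components: int
    n_degenerate_faces: int
    bbox_extent: np.ndarray
    unit_warning: bool

    def to_dict(self) -> dict:
        return {
            "watertight": self.watertight,
            "n_components": self.n_components,
            "n_degenerate_faces": self.n_degenerate_faces,
            "bbox_extent": [float(x) for x in self.bbox_extent],
            "unit_warning": self.unit_warning,
        }


# ---------------------------------------------------------------------------
# mesh cleanup


def merge_duplicate_vertices(mesh: TriangleMesh, tol: float = MERGE_TOL) -> TriangleMesh:
    """Merge vertices closer than ``tol`` and drop unreferenced/degenerate entries."""
    if not len(mesh.faces):
        raise InputError("mesh has zero faces")
    quantized = np.round(mesh.vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(quantized, axis=0, return_index=True, return_inverse=True)
    new_faces = inverse[mesh.faces]
    # drop faces collapsed to fewer than 3 distinct vertices
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    new_faces = new_faces[ok]
    # keep only referenced vertices, preserving order of first appearance
    referenced = np.zeros(len(first), dtype=bool)
    referenced[new_faces.ravel()] = True
    remap = -np.ones(len(first), dtype=np.int64)
    remap[referenced] = np.arange(referenced.sum())
    return TriangleMesh(mesh.vertices[first][referenced], remap[new_faces], dict(mesh.metadata))


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Report-only geometry checks: watertightness, components, degenerate faces,
    bounding box, and a unit heuristic (extent outside 120-400 mm warns)."""
    if not len(mesh.faces):
        raise InputError("cannot validate an empty mesh")
    extent = mesh.bounds[1] - mesh.bounds[0]
    max_extent = float(extent.max())
    return ValidationReport(
        watertight=mesh.is_watertight(),
        n_components=mesh.n_components(),
        n_degenerate_faces=int((mesh.face_areas() < _DEGENERATE_AREA).sum()),
        bbox_extent=extent,
        unit_warning=not (_UNIT_RANGE[0] <= max_extent <= _UNIT_RANGE[1]),
    )


# ---------------------------------------------------------------------------
# mesh readers


def read_mesh(path, fmt: str = "auto") -> TriangleMesh:
    """Read a triangle mesh (OBJ/PLY/STL), merge duplicate vertices and drop
    unreferenced ones.  ``fmt='auto'`` dispatches on the file extension."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mesh file not found: {path}")
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("obj", "ply", "stl"):
        raise InputError(f"unsupported mesh format: {fmt!r}")
    try:
        if fmt == "obj":
            verts, faces = _read_obj(path)
        elif fmt == "ply":
            verts, faces = _read_ply(path)
        else:
            verts, faces = _read_stl(path)
    except (InputError, GeometryError):
        raise
    except Exception as exc:  # malformed file content
        raise InputError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if len(faces) == 0:
        raise InputError(f"mesh has zero faces: {path}")
    mesh = merge_duplicate_vertices(TriangleMesh(verts, faces))
    mesh.metadata["source_path"] = str(path)
    log.info("read %s: %d vertices, %d faces", path, mesh.n_vertices, mesh.n_faces)
    return mesh


def _read_obj(path: Path):
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(tok.split("/")[0]) for tok in parts[1:]]
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                for k in range(1, len(idx) - 1):  # fan-triangulate polygons
                    faces.append([idx[0], idx[k], idx[k + 1]])
    return np.asarray(verts, float).reshape(-1, 3), np.asarray(faces, int).reshape(-1, 3)


_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def _read_ply(path: Path):
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise InputError(f"not a PLY file: {path}")
        fmt = None
        elements = []  # (name, count, [(prop_name, dtype) or ('list', count_t, item_t, name)])
        while True:
            line = fh.readline()
            if not line:
                raise InputError("unexpected EOF in PLY header")
            tokens = line.decode("ascii").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    elements[-1][2].append(("list", _PLY_TYPES[tokens[2]], _PLY_TYPES[tokens[3]], tokens[4]))
                else:
                    elements[-1][2].append((tokens[2], _PLY_TYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt == "ascii":
            return _read_ply_ascii(fh, elements)
        if fmt == "binary_little_endian":
            return _read_ply_binary(fh, elements, "<")
        if fmt == "binary_big_endian":
            return _read_ply_binary(fh, elements, ">")
        raise InputError(f"unsupported PLY format: {fmt}")


def _ply_extract(vertex_rows, face_rows):
    verts = np.asarray(vertex_rows, float)[:, :3]
    faces = []
    for row in face_rows:
        for k in range(1, len(row) - 1):
            faces.append([row[0], row[k], row[k + 1]])
    return verts, np.asarray(faces, int).reshape(-1, 3)


def _read_ply_ascii(fh, elements):
    vertex_rows, face_rows = [], []
    for name, count, props in elements:
        for _ in range(count):
            tokens = fh.readline().split()
            if name == "vertex":
                vertex_rows.append([float(t) for t in tokens[:3]])
            elif name == "face":
                n = int(tokens[0])
                face_rows.append([int(t) for t in tokens[1:1 + n]])
    return _ply_extract(vertex_rows, face_rows)


def _read_ply_binary(fh, elements, endian):
    vertex_rows, face_rows = [], []
    for name, count, props in elements:
        if name == "vertex" and all(p[0] != "list" for p in props):
            dtype = np.dtype([(p[0], endian + p[1]) for p in props])
            data = np.frombuffer(fh.read(dtype.itemsize * count), dtype=dtype)
            vertex_rows = np.column_stack([data["x"], data["y"], data["z"]])
        else:
            for _ in range(count):
                row = []
                for p in props:
                    if p[0] == "list":
                        n = int(np.frombuffer(fh.read(np.dtype(p[1]).itemsize), dtype=endian + p[1])[0])
                        items = np.frombuffer(fh.read(np.dtype(p[2]).itemsize * n), dtype=endian + p[2])
                        row = list(items)
                    else:
                        fh.read(np.dtype(p[1]).itemsize)
                if name == "face":
                    face_rows.append(row)
    return _ply_extract(vertex_rows, face_rows)


def _read_stl(path: Path):
    raw = path.read_bytes()
    if len(raw) >= 84:
        (n_tri,) = struct.unpack("<I", raw[80:84])
        if len(raw) == 84 + 50 * n_tri and not raw[:5].lower() == b"solid":
            return _parse_stl_binary(raw, n_tri)
        if len(raw) == 84 + 50 * n_tri and raw[:5].lower() == b"solid":
            # binary file that starts with 'solid'; size check wins
            try:
                return _parse_stl_ascii(raw.decode("ascii"))
            except Exception:
                return _parse_stl_binary(raw, n_tri)
    return _parse_stl_ascii(raw.decode("ascii", errors="replace"))


def _parse_stl_binary(raw: bytes, n_tri: int):
    rec = np.frombuffer(raw[84:84 + 50 * n_tri], dtype=np.dtype(
        [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]))
    verts = rec["verts"].reshape(-1, 3).astype(np.float64)
    faces = np.arange(len(verts)).reshape(-1, 3)
    return verts, faces


def _parse_stl_ascii(text: str):
    verts = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            verts.append([float(x) for x in parts[1:4]])
    verts = np.asarray(verts, float).reshape(-1, 3)
    if len(verts) % 3:
        raise InputError("ascii STL vertex count not a multiple of 3")
    return verts, np.arange(len(verts)).reshape(-1, 3)


# ---------------------------------------------------------------------------
# mesh writers


def write_mesh(mesh: TriangleMesh, path, fmt: str = "auto", binary: bool = False) -> None:
    """Write a mesh as OBJ, PLY or STL.  ``binary`` selects the binary PLY/STL
    variants (OBJ is always ascii)."""
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "obj":
        _write_obj(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path, binary)
    elif fmt == "stl":
        _write_stl(mesh, path, binary)
    else:
        raise InputError(f"unsupported mesh format: {fmt!r}")
    log.info("wrote %s: %d vertices, %d faces", path, mesh.n_vertices, mesh.n_faces)


def _write_obj(mesh: TriangleMesh, path: Path):
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _write_ply(mesh: TriangleMesh, path: Path, binary: bool):
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt} 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(mesh.vertices.astype("<f8").tobytes())
            counts = np.full((mesh.n_faces, 1), 3, dtype="<u1")
            face_dtype = np.dtype([("n", "<u1"), ("idx", "<i4", 3)])
            rec = np.empty(mesh.n_faces, dtype=face_dtype)
            rec["n"] = counts.ravel()
            rec["idx"] = mesh.faces.astype("<i4")
            fh.write(rec.tobytes())
        else:
            lines = [f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}" for v in mesh.vertices]
            lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
            fh.write(("\n".join(lines) + "\n").encode("ascii"))


def _write_stl(mesh: TriangleMesh, path: Path, binary: bool):
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    normals = np.where(norms[:, None] > 0, normals / np.maximum(norms, 1e-30)[:, None], 0.0)
    if binary:
        rec = np.zeros(len(tri), dtype=np.dtype(
            [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]))
        rec["normal"] = normals
        rec["verts"] = tri
        with open(path, "wb") as fh:
            fh.write(b"\0" * 80)
            fh.write(struct.pack("<I", len(tri)))
            fh.write(rec.tobytes())
    else:
        with open(path, "w") as fh:
            fh.write("solid craniometrics\n")
            for n, t in zip(normals, tri):
                fh.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write("endsolid craniometrics\n")


# ---------------------------------------------------------------------------
# landmarks


def read_landmarks(path) -> LandmarkSet:
    """Read a 3-landmark file (JSON object or ``name,x,y,z`` CSV)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"landmark file not found: {path}")
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InputError(f"invalid JSON in {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise SchemaError("landmark JSON must be an object")
        points = {k: v for k, v in data.items() if k in LANDMARK_NAMES}
    else:
        points = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"name", "x", "y", "z"} <= set(reader.fieldnames):
                raise SchemaError("landmark CSV must have columns name,x,y,z")
            for row in reader:
                points[row["name"].strip()] = [float(row["x"]), float(row["y"]), float(row["z"])]
    missing = [n for n in LANDMARK_NAMES if n not in points]
    if missing:
        raise SchemaError(f"missing landmarks in {path}: {', '.join(missing)}")
    for name in LANDMARK_NAMES:
        if len(np.atleast_1d(points[name])) != 3:
            raise SchemaError(f"landmark {name!r} must have 3 coordinates")
    log.info("read landmarks from %s", path)
    return LandmarkSet(*(np.asarray(points[n], float) for n in LANDMARK_NAMES))


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {n: [float(x) for x in getattr(landmarks, n)] for n in LANDMARK_NAMES}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "x", "y", "z"])
            for n in LANDMARK_NAMES:
                p = getattr(landmarks, n)
                writer.writerow([n, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])
    log.info("wrote landmarks to %s", path)
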