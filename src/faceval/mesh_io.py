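"""Mesh and landmark containers plus OBJ / PLY / JSON readers and writers.

Coordinates are millimetres throughout.  The OBJ reader is deliberately
permissive (scanner exports vary): only ``v`` and ``f`` records are
interpreted, everything else is skipped with a debug log message.
Round-trips are lossless at double precision — coordinates are written
with 17 significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError, VocabularyError

log = logging.getLogger(__name__)

#: Controlled vocabulary of landmark names.  ``NasionSoft`` is the soft
#: tissue nasion used (with the canthi and nose tip) to seed registration;
#: ``N'`` is the same anatomical point in its anthropometric notation.
LANDMARK_VOCABULARY = frozenset({
    "Prn", "Ls", "Li", "Lch", "Rch", "Pg'", "Gn'", "Me'", "Sn", "Sto",
    "Sl", "CphL", "CphR", "Gl", "N'", "TragionL", "TragionR",
    "SuborbitalR", "CanthusL", "CanthusR", "NoseTip", "NasionSoft",
})


@dataclass
class TriangleMesh:
    """Triangulated surface: ``vertices`` (n, 3) mm, ``faces`` (m, 3) int.

    ``colors`` is an optional (n, 3) array of RGB values in [0, 1].
    Vertex order is significant and preserved by all I/O.
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if self.faces.size == 0:
            self.faces = self.faces.reshape(0, 3)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise ValidationError("vertex coordinates must be finite")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValidationError("face index out of range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2])
                    | (f[:, 0] == f[:, 2])).any():
                raise ValidationError("degenerate face (repeated vertex index)")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.float64)
            if self.colors.shape != (len(self.vertices), 3):
                raise ValidationError("colors must be (n, 3)")
            if self.colors.min() < 0 or self.colors.max() > 1:
                raise ValidationError("colors must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(),
            None if self.colors is None else self.colors.copy(),
        )

    def face_normals(self) -> np.ndarray:
        """Unit normals from the winding order (right-hand rule)."""
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals."""
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm


@dataclass
class LandmarkSet:
    """Named anatomical 3D points in mm, keyed by the controlled vocabulary."""

    points: dict = field(default_factory=dict)
    units: str = "mm"

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            if name not in LANDMARK_VOCABULARY:
                raise VocabularyError(
                    f"unknown landmark name {name!r}; allowed names: "
                    + ", ".join(sorted(LANDMARK_VOCABULARY))
                )
            p = np.asarray(p, dtype=np.float64)
            if p.shape != (3,):
                raise ValidationError(f"landmark {name!r} is not a 3-vector")
            if not np.isfinite(p).all():
                raise ValidationError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = p
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def names(self):
        return sorted(self.points)

    def require(self, names):
        from .errors import MissingLandmarkError
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing)

    def transformed(self, fn) -> "LandmarkSet":
        """New set with ``fn`` applied to a stacked (k, 3) array of points."""
        names = list(self.points)
        pts = np.asarray([self.points[n] for n in names])
        out = fn(pts)
        return LandmarkSet({n: out[i] for i, n in enumerate(names)},
                           units=self.units)


# ---------------------------------------------------------------------------
# Wavefront OBJ

def _parse_face_token(tok: str, line_no: int) -> int:
    head = tok.split("/")[0]
    try:
        idx = int(head)
    except ValueError:
        raise ParseError(f"line {line_no}: malformed face token {tok!r}") from None
    if idx < 0:
        raise ParseError(
            f"line {line_no}: negative (relative) OBJ indices are not supported"
        )
    return idx - 1  # OBJ is 1-based


def read_obj(path) -> TriangleMesh:
    """Read a Wavefront OBJ file; polygons are fan-triangulated.

    Only ``v`` and ``f`` records are interpreted; ``vt``/``vn``/materials
    are ignored.  Face indices are converted to 0-based.
    """
    vertices: list = []
    faces: list = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ParseError(f"line {line_no}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(parts[1]), float(parts[2]),
                                     float(parts[3])])
                except ValueError:
                    raise ParseError(
                        f"line {line_no}: malformed vertex coordinate"
                    ) from None
            elif tag == "f":
                if len(parts) < 4:
                    raise ParseError(f"line {line_no}: face needs >= 3 indices")
                idx = [_parse_face_token(t, line_no) for t in parts[1:]]
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0], idx[k], idx[k + 1]])
            else:
                log.debug("ignoring OBJ record %r at line %d", tag, line_no)
    if not vertices or not faces:
        raise ParseError(f"{path}: OBJ file must contain at least one 'v' and one 'f'")
    return TriangleMesh(np.array(vertices), np.array(faces))


def write_obj(mesh: TriangleMesh, path) -> None:
    """Write OBJ with 17-significant-digit coordinates (lossless round-trip)."""
    if mesh.n_faces == 0:
        raise ValidationError("refusing to write a mesh with no faces")
    if mesh.colors is not None:
        log.warning("OBJ has no standard vertex colors; colors dropped "
                    "(use write_ply_colored to keep them)")
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# ASCII PLY with vertex colors

def write_ply_colored(mesh: TriangleMesh, path) -> None:
    """Export an ASCII PLY with 8-bit vertex colors (round-half-up)."""
    if mesh.colors is None:
        raise ValidationError("mesh has no vertex colors")
    if mesh.n_faces == 0:
        raise ValidationError("refusing to write a mesh with no faces")
    rgb = np.floor(mesh.colors * 255.0 + 0.5).astype(int)  # round half up
    rgb = np.clip(rgb, 0, 255)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v, c in zip(mesh.vertices, rgb):
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {c[0]} {c[1]} {c[2]}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> TriangleMesh:
    """Minimal ASCII PLY reader (for round-trip testing of color exports)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != "ply":
        raise ParseError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    has_color = False
    i = 1
    while i < len(lines):
        parts = lines[i].split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:2] == ["property", "uchar"] and parts[2] in ("red", "r"):
            has_color = True
        elif parts == ["end_header"]:
            i += 1
            break
        i += 1
    body = lines[i:]
    verts, colors = [], []
    for ln in body[:n_vert]:
        vals = ln.split()
        verts.append([float(v) for v in vals[:3]])
        if has_color:
            colors.append([int(v) / 255.0 for v in vals[3:6]])
    faces = []
    for ln in body[n_vert:n_vert + n_face]:
        vals = [int(v) for v in ln.split()]
        if vals[0] != 3:
            raise ParseError(f"{path}: non-triangular PLY face")
        faces.append(vals[1:4])
    return TriangleMesh(np.array(verts), np.array(faces),
                        np.array(colors) if has_color else None)


# ---------------------------------------------------------------------------
# Landmark JSON

def read_landmarks(path) -> LandmarkSet:
    """Read the landmark JSON schema {"units": "mm", "landmarks": {...}}."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: invalid JSON ({e})") from None
    if not isinstance(doc, dict) or "landmarks" not in doc:
        raise ParseError(f"{path}: missing 'landmarks' object")
    return LandmarkSet(doc["landmarks"], units=doc.get("units", "mm"))


def write_landmarks(lms: LandmarkSet, path) -> None:
    doc = {
        "units": lms.units,
        "landmarks": {
            name: [float(f"{c:.17g}") for c in p]
            for name, p in sorted(lms.points.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
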