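"""Synthetic face-like surfaces with analytically known landmarks and errors.

The face is an anterior height field: over an elliptical domain in the
(x, z) plane (x transverse, +x left; z vertical, +z superior) the surface
depth along +y (anterior) is a smooth paraboloid dome plus Gaussian
features (nose ridge, lip rolls, chin boss, brow ridge).  All 22
vocabulary landmarks are placed at analytically defined surface points,
so downstream registration and deviation analyses can be checked against
exact ground truth.

Deformations model "reconstruction error": Gaussian radial-basis bumps
displace vertices (by default along the local vertex normal, so the bump
amplitude is exactly the point-to-surface deviation a perfect analysis
should recover), followed by an optional rigid perturbation and
isotropic sensor-like noise along vertex normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .mesh_io import LandmarkSet, TriangleMesh

__all__ = [
    "SyntheticFaceSpec", "Bump", "DeformationSpec",
    "generate_face", "apply_deformation", "study_like_deformation",
]

# Landmark layout in normalized coordinates (u = x / half_width,
# v = z / half_height).  Prn and NasionSoft sit at mirror-symmetric v so a
# featureless dome gives them equal anterior depth.
_LANDMARK_UV = {
    "Gl": (0.0, 0.60),
    "N'": (0.0, 0.45),
    "NasionSoft": (0.0, 0.45),
    "CanthusL": (0.40, 0.35),
    "CanthusR": (-0.40, 0.35),
    "SuborbitalR": (-0.35, 0.22),
    "TragionL": (1.0, 0.0),
    "TragionR": (-1.0, 0.0),
    "Prn": (0.0, -0.45),
    "NoseTip": (0.0, -0.45),
    "Sn": (0.0, -0.58),
    "CphL": (0.06, -0.64),
    "CphR": (-0.06, -0.64),
    "Ls": (0.0, -0.66),
    "Sto": (0.0, -0.72),
    "Lch": (0.22, -0.72),
    "Rch": (-0.22, -0.72),
    "Li": (0.0, -0.78),
    "Sl": (0.0, -0.84),
    "Pg'": (0.0, -0.86),
    "Gn'": (0.0, -0.90),
    "Me'": (0.0, -0.94),
}


@dataclass(frozen=True)
class SyntheticFaceSpec:
    """Parameters of the synthetic face height field (all lengths in mm)."""

    resolution: int = 81
    half_width: float = 70.0
    half_height: float = 90.0
    dome_depth: float = 30.0
    nose_amplitude: float = 12.0
    lip_amplitude: float = 2.5
    chin_amplitude: float = 3.0
    brow_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.resolution < 20:
            raise ValidationError(
                "resolution must be >= 20 to host the facial features")
        for name in ("half_width", "half_height", "dome_depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("nose_amplitude", "lip_amplitude", "chin_amplitude",
                     "brow_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def with_(self, **kw) -> "SyntheticFaceSpec":
        return replace(self, **kw)


def _height(spec: SyntheticFaceSpec, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Analytic anterior depth y = f(x, z) of the face surface."""
    w, h = spec.half_width, spec.half_height
    u = np.asarray(x, dtype=np.float64) / w
    v = np.asarray(z, dtype=np.float64) / h

    y = spec.dome_depth * np.clip(1.0 - u * u - v * v, 0.0, None)

    def gauss(amp, uc, vc, su, sv):
        return amp * np.exp(-((u - uc) ** 2) / (2 * su ** 2)
                            - ((v - vc) ** 2) / (2 * sv ** 2))

    y = y + gauss(spec.nose_amplitude, 0.0, -0.45, 0.10, 0.18)   # nose ridge
    y = y + gauss(spec.brow_amplitude, 0.0, 0.60, 0.50, 0.10)    # brow ridge
    y = y + gauss(spec.lip_amplitude, 0.0, -0.66, 0.25, 0.04)    # upper lip
    y = y + gauss(spec.lip_amplitude, 0.0, -0.78, 0.25, 0.04)    # lower lip
    y = y + gauss(spec.chin_amplitude, 0.0, -0.90, 0.15, 0.08)   # chin boss
    return y


def generate_face(spec: SyntheticFaceSpec) -> tuple[TriangleMesh, LandmarkSet]:
    """Build the height-field mesh and its 22 analytic landmarks.

    The mesh is a manifold grid triangulation of the elliptical domain,
    wound so face normals point anteriorly (+y).  Identical specs produce
    bit-identical output.
    """
    r = spec.resolution
    u = np.linspace(-1.0, 1.0, r)
    uu, vv = np.meshgrid(u, u, indexing="ij")      # uu: transverse, vv: vertical
    inside = uu ** 2 + vv ** 2 <= 1.0 + 1e-12

    x = uu * spec.half_width
    z = vv * spec.half_height
    y = _height(spec, x, z)
    verts = np.stack([x.ravel(), y.ravel(), z.ravel()], axis=1)

    idx = np.arange(r * r).reshape(r, r)
    ok = (inside[:-1, :-1] & inside[1:, :-1]
          & inside[:-1, 1:] & inside[1:, 1:])
    i00 = idx[:-1, :-1][ok]
    i10 = idx[1:, :-1][ok]
    i01 = idx[:-1, 1:][ok]
    i11 = idx[1:, 1:][ok]
    # winding chosen so normals have +y (anterior) orientation
    faces = np.concatenate([
        np.stack([i00, i01, i11], axis=1),
        np.stack([i00, i11, i10], axis=1),
    ])

    used = np.zeros(r * r, dtype=bool)
    used[faces.ravel()] = True
    remap = -np.ones(r * r, dtype=np.int64)
    remap[used] = np.arange(used.sum())
    mesh = TriangleMesh(verts[used], remap[faces])

    lms = {}
    for name, (lu, lv) in _LANDMARK_UV.items():
        lx = lu * spec.half_width
        lz = lv * spec.half_height
        ly = float(_height(spec, np.array(lx), np.array(lz)))
        lms[name] = np.array([lx, ly, lz])
    return mesh, LandmarkSet(lms)


# ---------------------------------------------------------------------------
# Deformation


@dataclass(frozen=True)
class Bump:
    """Gaussian radial-basis displacement bump.

    ``center`` is a landmark name or a 3D point; ``direction`` is a 3-vector
    or the string "normal" (displace along the local vertex normal).
    """

    center: object
    width: float
    amplitude: float
    direction: object = "normal"

    def __post_init__(self):
        if self.width <= 0:
            raise ValidationError("bump width must be > 0")


@dataclass(frozen=True)
class DeformationSpec:
    bumps: tuple = ()
    rotvec_deg: tuple = (0.0, 0.0, 0.0)   # axis-angle, norm = angle in degrees
    translation: tuple = (0.0, 0.0, 0.0)  # mm
    noise_sd: float = 0.0                 # mm, along vertex normals
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")
        object.__setattr__(self, "bumps", tuple(self.bumps))

    @property
    def rigid(self) -> tuple[np.ndarray, np.ndarray]:
        rot = Rotation.from_rotvec(np.asarray(self.rotvec_deg, dtype=float),
                                   degrees=True)
        return rot.as_matrix(), np.asarray(self.translation, dtype=float)


def _resolve_center(center, lms: LandmarkSet) -> np.ndarray:
    if isinstance(center, str):
        if center not in lms:
            raise ValidationError(f"unresolvable bump anchor {center!r}")
        return lms[center]
    c = np.asarray(center, dtype=np.float64)
    if c.shape != (3,):
        raise ValidationError("bump center must be a landmark name or 3-vector")
    return c


def _bump_displacement(points: np.ndarray, normals: np.ndarray,
                       bumps, lms: LandmarkSet) -> np.ndarray:
    disp = np.zeros_like(points)
    for bump in bumps:
        c = _resolve_center(bump.center, lms)
        r2 = ((points - c) ** 2).sum(axis=1)
        g = bump.amplitude * np.exp(-r2 / (2.0 * bump.width ** 2))
        if isinstance(bump.direction, str) and bump.direction == "normal":
            d = normals
        else:
            d = np.asarray(bump.direction, dtype=np.float64)
            d = d / np.linalg.norm(d)
            d = np.broadcast_to(d, points.shape)
        disp = disp + g[:, None] * d
    return disp


def apply_deformation(mesh: TriangleMesh, lms: LandmarkSet,
                      spec: DeformationSpec):
    """Deform a face pair: bumps, then rigid perturbation, then noise.

    Returns ``(mesh, landmarks, truth)`` where ``truth`` holds each
    vertex's pre-rigid displacement magnitude (mm) — the ground truth a
    deviation analysis must recover.  Landmarks are transported by the
    same bump + rigid map but receive no noise.
    """
    normals = mesh.vertex_normals()
    disp = _bump_displacement(mesh.vertices, normals, spec.bumps, lms)
    truth = np.linalg.norm(disp, axis=1)
    v = mesh.vertices + disp

    rot, t = spec.rigid
    v = v @ rot.T + t

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        n = TriangleMesh(v, mesh.faces).vertex_normals()
        v = v + spec.noise_sd * rng.standard_normal(len(v))[:, None] * n

    # landmarks: bump displacement via the nearest vertex's normal
    tree = cKDTree(mesh.vertices)
    names = list(lms.points)
    pts = np.asarray([lms[n] for n in names])
    _, nearest = tree.query(pts)
    lm_disp = _bump_displacement(pts, normals[nearest], spec.bumps, lms)
    lm_out = (pts + lm_disp) @ rot.T + t
    out_lms = LandmarkSet({n: lm_out[i] for i, n in enumerate(names)},
                          units=lms.units)
    return TriangleMesh(v, mesh.faces.copy()), out_lms, truth


def study_like_deformation(face: SyntheticFaceSpec, seed: int = 0,
                           noise_sd: float = 0.05) -> DeformationSpec:
    """Deformation emulating the study's error pattern.

    Largest errors at the forehead (anterior) and cheeks (posterior) with
    0.5-3 mm bump amplitudes — the opposite signs keep best-fit
    registration from absorbing the discrepancy — plus a moderate rigid
    misalignment and sub-0.1 mm sensor noise.
    """
    rng = np.random.default_rng(seed)
    w, h = face.half_width, face.half_height
    cheek_u, cheek_v = 0.55, -0.05

    def amp(lo, hi):
        return float(rng.uniform(lo, hi))

    bumps = (
        Bump(center="Gl", width=0.45 * w, amplitude=amp(2.8, 3.0)),
        Bump(center=np.array([cheek_u * w, 12.0, cheek_v * h]),
             width=0.30 * w, amplitude=-amp(2.8, 3.0)),
        Bump(center=np.array([-cheek_u * w, 12.0, cheek_v * h]),
             width=0.30 * w, amplitude=-amp(2.8, 3.0)),
        Bump(center=np.array([0.18 * w, 25.0, -0.50 * h]),
             width=0.10 * w, amplitude=amp(1.2, 1.8)),
        Bump(center=np.array([-0.18 * w, 25.0, -0.50 * h]),
             width=0.10 * w, amplitude=amp(1.2, 1.8)),
        Bump(center="Sto", width=0.13 * w, amplitude=amp(1.1, 1.5)),
    )
    rotvec = rng.uniform(-1.0, 1.0, size=3)
    rotvec *= rng.uniform(2.0, 8.0) / np.linalg.norm(rotvec)
    translation = rng.uniform(-5.0, 5.0, size=3)
    return DeformationSpec(bumps=bumps, rotvec_deg=tuple(rotvec),
                           translation=tuple(translation),
                           noise_sd=noise_sd, seed=seed)
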