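"""Anatomical frame, signed surface-deviation fields, RMSE and color maps.

The facial frame has its origin at the midpoint of the bilateral tragion,
x through the tragions (left positive), the x-y plane through both
tragions and the right suborbital point (soft tissue Frankfort
horizontal), y anterior and z superior positive.  Signed point-to-surface
deviations take their sign from the reference surface's winding normals
(the synthetic generator winds faces so normals point anteriorly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (DegenerateGeometryError, MissingLandmarkError,
                     ValidationError)
from .geometry import SurfaceIndex
from .mesh_io import LandmarkSet, TriangleMesh

__all__ = [
    "FacialFrame", "DeviationField", "DeviationSummary", "LandmarkDeviation",
    "build_facial_frame", "crop_region", "deviation_field", "rmse",
    "cohort_summary", "landmark_deviation", "colorize",
    "REGION_LANDMARKS",
]

REGION_LANDMARKS = {
    "facial": ("TragionL", "TragionR", "Me'", "Gl"),
    "perioral": ("Sn", "Me'", "Lch", "Rch"),
}


@dataclass(frozen=True)
class FacialFrame:
    """Orthonormal right-handed anatomical frame (axes are rows of unit vectors)."""

    origin: np.ndarray
    x_axis: np.ndarray  # transverse, left +
    y_axis: np.ndarray  # anteroposterior, anterior +
    z_axis: np.ndarray  # vertical, superior +

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.float64))
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-9):
            raise ValidationError("frame axes must be orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis,
                           atol=1e-9):
            raise ValidationError("frame must be right-handed (x cross y = z)")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World points -> frame coordinates (columns x, y, z)."""
        points = np.asarray(points, dtype=np.float64)
        rel = points - self.origin
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        return rel @ axes.T


@dataclass
class DeviationField:
    """Signed point-to-surface distances sampled at test points."""

    points: np.ndarray
    signed_distances: np.ndarray
    region: str = "facial"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.signed_distances = np.asarray(self.signed_distances,
                                           dtype=np.float64)
        if len(self.signed_distances) < 1:
            raise ValidationError("deviation field must contain >= 1 sample")
        if len(self.points) != len(self.signed_distances):
            raise ValidationError("points and distances must align")

    @property
    def n(self) -> int:
        return len(self.signed_distances)


@dataclass(frozen=True)
class DeviationSummary:
    rmse: float
    mean: float
    sd: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class LandmarkDeviation:
    """Total and per-axis absolute deviations of one landmark (mm)."""

    d: float
    dx: float
    dy: float
    dz: float


def build_facial_frame(lms: LandmarkSet) -> FacialFrame:
    """Frame from the bilateral tragions, right suborbital point and Prn."""
    lms.require(("TragionL", "TragionR", "SuborbitalR", "Prn"))
    tl, tr = lms["TragionL"], lms["TragionR"]
    so, prn = lms["SuborbitalR"], lms["Prn"]

    origin = (tl + tr) / 2.0
    span = tl - tr
    if np.linalg.norm(span) < 1e-9:
        raise DegenerateGeometryError("tragions coincide")
    x_axis = span / np.linalg.norm(span)

    normal = np.cross(span, so - tr)
    if np.linalg.norm(normal) < 1e-9 * max(np.linalg.norm(span), 1.0):
        raise DegenerateGeometryError(
            "SuborbitalR lies on the tragion line; FH plane undefined")
    z_axis = normal / np.linalg.norm(normal)
    y_axis = np.cross(z_axis, x_axis)
    if np.dot(y_axis, prn - origin) < 0:   # anterior must be positive
        z_axis = -z_axis
        y_axis = -y_axis
    return FacialFrame(origin, x_axis, y_axis, z_axis)


def crop_region(mesh: TriangleMesh, lms: LandmarkSet, frame: FacialFrame,
                region: str, return_index: bool = False):
    """Landmark-driven region crop in frame coordinates.

    facial: z between z(Me') - 5 mm and z(Gl) + 10 mm, x between the
    tragions.  perioral: z in [z(Me'), z(Sn)], |x| <= 1.2 * cheilion
    half-width.  Faces survive iff all three vertices survive.
    """
    if region not in REGION_LANDMARKS:
        raise ValidationError(f"unknown region {region!r}")
    lms.require(REGION_LANDMARKS[region])

    q = frame.to_frame(mesh.vertices)
    lm_frame = {n: frame.to_frame(lms[n]) for n in REGION_LANDMARKS[region]}

    if region == "facial":
        z_lo = lm_frame["Me'"][2] - 5.0
        z_hi = lm_frame["Gl"][2] + 10.0
        x_lo = min(lm_frame["TragionL"][0], lm_frame["TragionR"][0])
        x_hi = max(lm_frame["TragionL"][0], lm_frame["TragionR"][0])
        keep = ((q[:, 2] >= z_lo) & (q[:, 2] <= z_hi)
                & (q[:, 0] >= x_lo) & (q[:, 0] <= x_hi))
    else:
        z_lo = lm_frame["Me'"][2]
        z_hi = lm_frame["Sn"][2]
        half = 1.2 * max(abs(lm_frame["Lch"][0]), abs(lm_frame["Rch"][0]))
        keep = ((q[:, 2] >= z_lo) & (q[:, 2] <= z_hi)
                & (np.abs(q[:, 0]) <= half))

    if not keep.any():
        raise ValidationError(f"{region} crop is empty")
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    idx = np.nonzero(keep)[0]
    remap[idx] = np.arange(len(idx))
    face_keep = keep[mesh.faces].all(axis=1)
    faces = remap[mesh.faces[face_keep]]
    colors = None if mesh.colors is None else mesh.colors[idx]
    cropped = TriangleMesh(mesh.vertices[idx], faces, colors)
    if return_index:
        return cropped, idx
    return cropped


def deviation_field(test: TriangleMesh, reference: TriangleMesh,
                    region: str = "facial",
                    surface: SurfaceIndex | None = None) -> DeviationField:
    """Signed closest-point distance from every test vertex to the reference.

    The sign comes from the reference winding normal at the closest
    triangle: positive where the test point lies on the outward (anterior)
    side.  The test mesh must already be registered to the reference.
    """
    if test.n_vertices == 0:
        raise ValidationError("test mesh is empty")
    if reference.n_faces == 0:
        raise ValidationError("reference mesh has no faces")
    surface = surface or SurfaceIndex(reference)
    dist, closest, tri = surface.query(test.vertices)
    normal = surface.face_normals[tri]
    side = np.einsum("ij,ij->i", test.vertices - closest, normal)
    signed = np.where(side >= 0, dist, -dist)
    return DeviationField(test.vertices, signed, region)


def rmse(field: DeviationField) -> DeviationSummary:
    """RMSE = sqrt(mean of squared signed distances), plus mean and SD."""
    d = field.signed_distances
    value = float(np.sqrt(np.mean(d ** 2)))
    sd = float(np.std(d, ddof=1)) if field.n > 1 else 0.0
    return DeviationSummary(rmse=value, mean=float(np.mean(d)), sd=sd,
                            n=field.n)


def cohort_summary(per_model_rmse) -> DeviationSummary:
    """Mean, SD (n-1) and t-based 95% CI of a cohort of per-model RMSEs."""
    values = np.asarray(per_model_rmse, dtype=np.float64)
    n = len(values)
    if n < 2:
        raise ValidationError("cohort summary needs >= 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return DeviationSummary(rmse=mean, mean=mean, sd=sd, n=n,
                            ci_low=mean - half, ci_high=mean + half)


def landmark_deviation(test_lms: LandmarkSet, ref_lms: LandmarkSet,
                       frame: FacialFrame, names=None) -> dict:
    """Per-landmark total and per-axis absolute deviations in frame coords."""
    if names is None:
        names = ref_lms.names()
    out = {}
    for name in names:
        missing = [n for n in (name,) if n not in test_lms or n not in ref_lms]
        if missing:
            raise MissingLandmarkError(missing)
        delta = test_lms[name] - ref_lms[name]
        comp = np.array([np.dot(delta, frame.x_axis),
                         np.dot(delta, frame.y_axis),
                         np.dot(delta, frame.z_axis)])
        out[name] = LandmarkDeviation(d=float(np.linalg.norm(comp)),
                                      dx=float(abs(comp[0])),
                                      dy=float(abs(comp[1])),
                                      dz=float(abs(comp[2])))
    return out


def _diverging_palette(t: np.ndarray) -> np.ndarray:
    """Blue -> green -> red over t in [0, 1] (0.5 maps to pure green)."""
    t = np.clip(t, 0.0, 1.0)
    rgb = np.zeros((len(t), 3))
    lo = t < 0.5
    s = t[lo] * 2.0
    rgb[lo, 2] = 1.0 - s       # blue fades out
    rgb[lo, 1] = s
    s = (t[~lo] - 0.5) * 2.0
    rgb[~lo, 1] = 1.0 - s
    rgb[~lo, 0] = s            # red fades in
    return rgb


def colorize(field: DeviationField, test: TriangleMesh,
             limit: float) -> TriangleMesh:
    """Color the test mesh by signed deviation on [-limit, +limit], clamped."""
    if limit <= 0:
        raise ValidationError("color limit must be > 0")
    if field.n != test.n_vertices:
        raise ValidationError("field must be sampled at the test vertices")
    t = (field.signed_distances + limit) / (2.0 * limit)
    colors = _diverging_palette(t)
    return TriangleMesh(test.vertices.copy(), test.faces.copy(), colors)
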