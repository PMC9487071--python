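"""Two-step rigid registration: landmark seeding plus best-fit ICP.

Stage one solves the least-squares rigid transform over four named
landmark pairs (both canthi, nose tip, soft tissue nasion) with the
Kabsch/SVD algorithm.  Stage two refines it with point-to-surface ICP:
sampled test vertices are matched to their exact closest points on the
reference surface, pairs farther than the rejection tolerance are
dropped, and the rigid update is re-estimated until the RMS change falls
below the convergence threshold (after a mandatory minimum number of
iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateGeometryError, MissingLandmarkError,
                     NoOverlapError, ValidationError)
from .geometry import SurfaceIndex
from .mesh_io import LandmarkSet, TriangleMesh

__all__ = ["RigidTransform", "IcpParams", "IcpResult", "TwoStepResult",
           "kabsch_align", "icp_refine", "two_step_register",
           "REGISTRATION_LANDMARKS"]

#: Landmarks driving the coarse (stage-one) alignment.
REGISTRATION_LANDMARKS = ("CanthusL", "CanthusR", "NoseTip", "NasionSoft")


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation, applied as ``p -> R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        rot = np.asarray(self.rotation, dtype=np.float64)
        t = np.asarray(self.translation, dtype=np.float64)
        if rot.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation 3")
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-9):
            raise ValidationError("rotation determinant must be +1")
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass(frozen=True)
class IcpParams:
    """ICP controls; defaults honor "at least 50 iterations", a convergence
    threshold well below 0.1 mm, full (100%) vertex sampling and a 2 mm
    correspondence rejection tolerance."""

    min_iterations: int = 50
    max_iterations: int = 500
    threshold: float = 1e-3        # mm, on RMS change
    tolerance: float = 2.0         # mm, correspondence rejection
    sampling_fraction: float = 1.0

    def __post_init__(self):
        if self.min_iterations > self.max_iterations:
            raise ValidationError("min_iterations must be <= max_iterations")
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if not (0 < self.sampling_fraction <= 1):
            raise ValidationError("sampling_fraction must be in (0, 1]")


@dataclass
class IcpResult:
    transform: RigidTransform
    rms: float
    rms_log: list = field(default_factory=list)
    rejected_log: list = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.rms_log)


@dataclass
class TwoStepResult:
    transform: RigidTransform
    landmark_rms: float
    surface_rms: float
    icp: IcpResult


def kabsch_align(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Reflections are excluded by flipping the sign of the smallest
    singular direction when the raw solution has determinant -1.
    """
    src = np.atleast_2d(np.asarray(src, dtype=np.float64))
    dst = np.atleast_2d(np.asarray(dst, dtype=np.float64))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValidationError("src and dst must be matching (n, 3) arrays")
    if len(src) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")

    c_src = src.mean(axis=0)
    c_dst = dst.mean(axis=0)
    p = src - c_src
    q = dst - c_dst

    # collinearity check on both clouds
    for cloud, label in ((p, "src"), (q, "dst")):
        s = np.linalg.svd(cloud, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegenerateGeometryError(f"{label} points are collinear")

    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = c_dst - rot @ c_src
    return RigidTransform(rot, t)


def _sample_indices(n: int, fraction: float) -> np.ndarray:
    m = max(3, int(round(n * fraction)))
    if m >= n:
        return np.arange(n)
    return np.unique(np.round(np.linspace(0, n - 1, m)).astype(np.int64))


def icp_refine(test: TriangleMesh, reference: TriangleMesh,
               init: RigidTransform, params: IcpParams | None = None,
               surface: SurfaceIndex | None = None) -> IcpResult:
    """Refine ``init`` by point-to-surface ICP of ``test`` onto ``reference``."""
    params = params or IcpParams()
    if test.n_vertices == 0 or reference.n_faces == 0:
        raise ValidationError("both meshes must be non-empty")
    surface = surface or SurfaceIndex(reference)
    sample = test.vertices[_sample_indices(test.n_vertices,
                                           params.sampling_fraction)]

    transform = init
    prev_rms = np.inf
    rms_log: list[float] = []
    rejected_log: list[int] = []
    for it in range(params.max_iterations):
        moved = transform.apply(sample)
        dist, closest, _ = surface.query(moved)
        keep = dist <= params.tolerance
        rejected_log.append(int((~keep).sum()))
        if not keep.any():
            raise NoOverlapError(it)
        delta = kabsch_align(moved[keep], closest[keep])
        transform = delta.compose(transform)
        res = delta.apply(moved[keep]) - closest[keep]
        rms = float(np.sqrt((res ** 2).sum(axis=1).mean()))
        rms_log.append(rms)
        if it + 1 >= params.min_iterations and abs(prev_rms - rms) < params.threshold:
            break
        prev_rms = rms
    return IcpResult(transform, rms_log[-1], rms_log, rejected_log)


def two_step_register(test: TriangleMesh, reference: TriangleMesh,
                      test_lms: LandmarkSet, reference_lms: LandmarkSet,
                      params: IcpParams | None = None) -> TwoStepResult:
    """Landmark seeding (4 pairs) followed by best-fit ICP refinement."""
    for lms, label in ((test_lms, "test"), (reference_lms, "reference")):
        missing = [n for n in REGISTRATION_LANDMARKS if n not in lms]
        if missing:
            raise MissingLandmarkError(missing)

    src = np.asarray([test_lms[n] for n in REGISTRATION_LANDMARKS])
    dst = np.asarray([reference_lms[n] for n in REGISTRATION_LANDMARKS])
    coarse = kabsch_align(src, dst)
    landmark_rms = float(np.sqrt(
        ((coarse.apply(src) - dst) ** 2).sum(axis=1).mean()))

    icp = icp_refine(test, reference, coarse, params)
    return TwoStepResult(icp.transform, landmark_rms, icp.rms, icp)
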