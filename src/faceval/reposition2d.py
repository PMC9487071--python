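"""Geometric repositioning of front/lateral 2D photos.

Raster convention throughout: the image y axis points down.  A positive
angle denotes the rotation that, applied with :func:`rotate_points`,
turns a direction of positive raster angle back to horizontal (i.e. the
image appears rotated counterclockwise on screen).  The module computes
angles only; pixel resampling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateGeometryError, InfeasibleError,
                     MissingLandmarkError, ValidationError)

__all__ = ["PhotoLandmarks2D", "rotate_points", "front_leveling_angle",
           "h1", "lateral_rotation_angle"]

_KNOWN_2D = {"CanthusL", "CanthusR", "Cheilion", "Trichion", "Prn", "Me'"}


@dataclass
class PhotoLandmarks2D:
    """Named 2D pixel points on a photo; y grows downward."""

    points: dict = field(default_factory=dict)
    pixel_pitch: float | None = None  # mm per pixel, optional

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            if name not in _KNOWN_2D:
                raise ValidationError(f"unknown 2D landmark {name!r}")
            p = np.asarray(p, dtype=np.float64)
            if p.shape != (2,):
                raise ValidationError(f"landmark {name!r} is not a 2-vector")
            if not np.isfinite(p).all():
                raise ValidationError(f"landmark {name!r} is not finite")
            clean[name] = p
        self.points = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def require(self, names):
        missing = [n for n in names if n not in self.points]
        if missing:
            raise MissingLandmarkError(missing)


def rotate_points(points: np.ndarray, angle_deg: float,
                  center=(0.0, 0.0)) -> np.ndarray:
    """Apply the module's rotation convention about ``center``.

    A point at raster angle ``a`` (atan2(y, x), y down) moves to angle
    ``a - angle_deg``, so applying ``front_leveling_angle`` levels the
    canthus line.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    center = np.asarray(center, dtype=np.float64)
    th = np.radians(angle_deg)
    rot = np.array([[np.cos(th), np.sin(th)],
                    [-np.sin(th), np.cos(th)]])
    return (points - center) @ rot.T + center


def front_leveling_angle(lms: PhotoLandmarks2D) -> float:
    """Rotation (degrees, in (-90, 90]) leveling the lateral-canthus line."""
    lms.require(("CanthusL", "CanthusR"))
    d = lms["CanthusL"] - lms["CanthusR"]
    if np.linalg.norm(d) < 1e-12:
        raise DegenerateGeometryError("canthi coincide")
    angle = float(np.degrees(np.arctan2(d[1], d[0])))
    while angle <= -90.0:
        angle += 180.0
    while angle > 90.0:
        angle -= 180.0
    return angle


def h1(lms: PhotoLandmarks2D, side: str = "L",
       assume_leveled: bool = False) -> float:
    """Vertical canthus-to-cheilion drop (pixels), measured after leveling.

    ``side`` selects which canthus anchors the measurement.  When both
    canthi are present and ``assume_leveled`` is false, the leveling
    rotation is applied first; otherwise coordinates are used as given.
    """
    canthus_name = "CanthusL" if side.upper() == "L" else "CanthusR"
    lms.require((canthus_name, "Cheilion"))
    canthus = lms[canthus_name]
    cheilion = lms["Cheilion"]
    if not assume_leveled and "CanthusL" in lms and "CanthusR" in lms:
        angle = front_leveling_angle(lms)
        canthus, cheilion = rotate_points(
            np.stack([canthus, cheilion]), angle)
    return float(abs(cheilion[1] - canthus[1]))


def lateral_rotation_angle(canthus, cheilion, target_h1: float) -> float:
    """Rotation about the canthus giving the target vertical drop of cheilion.

    Of the two trigonometric solutions the smallest-magnitude one is
    returned; both keep the cheilion below the canthus (y down) for a
    non-negative target.
    """
    canthus = np.asarray(canthus, dtype=np.float64)
    cheilion = np.asarray(cheilion, dtype=np.float64)
    v = cheilion - canthus
    length = float(np.linalg.norm(v))
    if length < 1e-12:
        raise DegenerateGeometryError("cheilion coincides with canthus")
    if target_h1 < 0:
        raise ValidationError("target H1 must be >= 0")
    if target_h1 > length + 1e-12:
        raise InfeasibleError(
            f"target H1 {target_h1:g} exceeds the canthus-cheilion "
            f"distance {length:g}")
    phi = np.degrees(np.arctan2(v[1], v[0]))
    alpha = np.degrees(np.arcsin(min(target_h1 / length, 1.0)))
    candidates = [phi - alpha, phi - (180.0 - alpha)]
    candidates = [((c + 180.0) % 360.0) - 180.0 for c in candidates]
    return float(min(candidates, key=abs))
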