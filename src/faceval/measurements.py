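"""The 12 soft-tissue linear and angular measurements.

Linear values are 3D Euclidean inter-landmark distances in mm; angles
are in decimal degrees at the middle (vertex) landmark.  All values are
invariant under rigid motion of the landmark set.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError
from .mesh_io import LandmarkSet

__all__ = ["LINEAR_MEASUREMENTS", "ANGULAR_MEASUREMENTS",
           "linear_measure", "angle_measure", "measure_all"]

#: name -> (a, b) landmark pair, distance in mm
LINEAR_MEASUREMENTS = {
    "UpperLipHeight": ("Sn", "Sto"),
    "LowerLipHeight": ("Sl", "Li"),
    "UpperVermilionHeight": ("Ls", "Sto"),
    "LowerVermilionHeight": ("Li", "Sto"),
    "PhiltralLength": ("Sn", "Ls"),
    "PhiltralWidth": ("CphR", "CphL"),
    "LabialFissureWidth": ("Lch", "Rch"),
    "FacialHeight": ("N'", "Gn'"),
}

#: name -> (a, vertex, b) landmark triple, angle at vertex in degrees
ANGULAR_MEASUREMENTS = {
    "NasolabialAngle": ("Prn", "Sn", "Ls"),
    "FacialConvexity": ("Gl", "Sn", "Pg'"),
    "NasalAngle": ("N'", "Prn", "Sn"),
    "NasofrontalAngle": ("Gl", "N'", "Prn"),
}


def linear_measure(lms: LandmarkSet, a: str, b: str) -> float:
    """Euclidean distance between two landmarks, in mm."""
    lms.require((a, b))
    return float(np.linalg.norm(lms[a] - lms[b]))


def angle_measure(lms: LandmarkSet, a: str, vertex: str, b: str) -> float:
    """Angle (degrees) at ``vertex`` between rays towards ``a`` and ``b``."""
    lms.require((a, vertex, b))
    ra = lms[a] - lms[vertex]
    rb = lms[b] - lms[vertex]
    na, nb = np.linalg.norm(ra), np.linalg.norm(rb)
    if na < 1e-12 or nb < 1e-12:
        raise DegenerateGeometryError(
            f"degenerate ray at angle {a}-{vertex}-{b}")
    cosine = np.clip(np.dot(ra, rb) / (na * nb), -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cosine)))
    if angle >= 180.0 - 1e-12:
        warnings.warn(f"angle {a}-{vertex}-{b} is a straight line (180 deg)",
                      stacklevel=2)
    return angle


def measure_all(lms: LandmarkSet) -> dict:
    """All 12 measurements as an ordered name -> value map."""
    needed = sorted({n for pair in LINEAR_MEASUREMENTS.values() for n in pair}
                    | {n for tri in ANGULAR_MEASUREMENTS.values() for n in tri})
    missing = [n for n in needed if n not in lms]
    if missing:
        raise MissingLandmarkError(missing)
    out = {}
    for name, (a, b) in LINEAR_MEASUREMENTS.items():
        out[name] = linear_measure(lms, a, b)
    for name, (a, v, b) in ANGULAR_MEASUREMENTS.items():
        out[name] = angle_measure(lms, a, v, b)
    return out
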