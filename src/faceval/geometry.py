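"""Exact closest-point queries against a triangulated surface.

The query structure combines a KD-tree over triangle centroids with an
exact point-to-triangle solve over the candidate set.  A bound check
(`best distance` vs `k-th centroid distance - max triangle radius`)
guarantees the returned point is the true global closest point; points
failing the bound fall back to a ball query.  Ties between triangles are
broken by the lowest triangle index for determinism.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .mesh_io import TriangleMesh

__all__ = ["closest_point_on_triangles", "SurfaceIndex"]


def closest_point_on_triangles(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                               c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a, b, c) to p, row-wise over (n, 3) arrays.

    Barycentric region classification (Ericson-style), fully vectorized.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    c = np.atleast_2d(np.asarray(c, dtype=np.float64))

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    res = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                      # vertex region A
    res[m] = a[m]
    done |= m

    m = ~done & (d3 >= 0) & (d4 <= d3)             # vertex region B
    res[m] = b[m]
    done |= m

    m = ~done & (d6 >= 0) & (d5 <= d6)             # vertex region C
    res[m] = c[m]
    done |= m

    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    if m.any():
        t = (d1[m] / (d1[m] - d3[m]))[:, None]
        res[m] = a[m] + t * ab[m]
    done |= m

    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    if m.any():
        t = (d2[m] / (d2[m] - d6[m]))[:, None]
        res[m] = a[m] + t * ac[m]
    done |= m

    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    if m.any():
        t = ((d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m])))[:, None]
        res[m] = b[m] + t * (c[m] - b[m])
    done |= m

    m = ~done                                      # interior
    if m.any():
        denom = (va + vb + vc)[m]
        v = (vb[m] / denom)[:, None]
        w = (vc[m] / denom)[:, None]
        res[m] = a[m] + v * ab[m] + w * ac[m]
    return res


class SurfaceIndex:
    """Accelerated exact closest-point queries on a triangle mesh."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise ValidationError("cannot build a surface index with zero faces")
        self.mesh = mesh
        self.tri = mesh.vertices[mesh.faces]          # (m, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        self._tree = cKDTree(self.centroids)
        # max distance from a centroid to its triangle's farthest vertex:
        # bounds how much closer a far-centroid triangle can get.
        self.r_max = float(
            np.sqrt(((self.tri - self.centroids[:, None, :]) ** 2)
                    .sum(axis=2)).max()
        )
        self.face_normals = mesh.face_normals()

    def query(self, points: np.ndarray, k: int = 32):
        """Return (distances, closest_points, triangle_indices) for each point."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n_tri = len(self.centroids)
        k = min(k, n_tri)
        d_cent, cand = self._tree.query(points, k=k)
        if k == 1:
            d_cent = d_cent[:, None]
            cand = cand[:, None]
        # sort candidates by triangle index so argmin tie-breaks low index
        order = np.argsort(cand, axis=1)
        cand = np.take_along_axis(cand, order, axis=1)
        kth_cent = d_cent[:, -1]

        flat = cand.ravel()
        tri = self.tri[flat]
        rep = np.repeat(points, k, axis=0)
        cp = closest_point_on_triangles(rep, tri[:, 0], tri[:, 1], tri[:, 2])
        cp = cp.reshape(len(points), k, 3)
        d = np.linalg.norm(cp - points[:, None, :], axis=2)
        j = np.argmin(d, axis=1)
        rows = np.arange(len(points))
        best_d = d[rows, j]
        best_cp = cp[rows, j]
        best_tri = cand[rows, j]

        if k < n_tri:
            # a triangle outside the candidate set has centroid distance
            # >= kth_cent, hence closest point >= kth_cent - r_max
            unsafe = np.nonzero(best_d > kth_cent - self.r_max)[0]
            for i in unsafe:
                ball = self._tree.query_ball_point(
                    points[i], best_d[i] + self.r_max)
                ball = np.sort(np.asarray(ball, dtype=np.int64))
                tri_b = self.tri[ball]
                pts = np.broadcast_to(points[i], (len(ball), 3))
                cp_b = closest_point_on_triangles(
                    pts, tri_b[:, 0], tri_b[:, 1], tri_b[:, 2])
                d_b = np.linalg.norm(cp_b - points[i], axis=1)
                jb = int(np.argmin(d_b))
                if d_b[jb] < best_d[i] or (
                        d_b[jb] == best_d[i] and ball[jb] < best_tri[i]):
                    best_d[i] = d_b[jb]
                    best_cp[i] = cp_b[jb]
                    best_tri[i] = ball[jb]
        return best_d, best_cp, best_tri
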