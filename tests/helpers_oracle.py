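"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive quantities with different algorithms than
the package (brute force, direct formulas), so they can serve as
independent checks.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


# --- point-to-triangle, via plane projection + edge clamping ---------------

def _point_segment(p, a, b):
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return a + t * ab


def point_triangle_oracle(p, a, b, c):
    """Closest point on a triangle by projection and barycentric test."""
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    q = p - np.dot(p - a, n) * n
    # barycentric coordinates of q
    v0, v1, v2 = b - a, c - a, q - a
    d00, d01, d11 = np.dot(v0, v0), np.dot(v0, v1), np.dot(v1, v1)
    d20, d21 = np.dot(v2, v0), np.dot(v2, v1)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    if v >= 0 and w >= 0 and v + w <= 1:
        return q
    candidates = [_point_segment(p, a, b), _point_segment(p, b, c),
                  _point_segment(p, a, c)]
    dists = [np.linalg.norm(p - c_) for c_ in candidates]
    return candidates[int(np.argmin(dists))]


def brute_closest_distance(mesh, points):
    """Min distance from each query point to any triangle (full scan)."""
    tri = mesh.vertices[mesh.faces]
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for a, b, c in tri:
            cp = point_triangle_oracle(p, a, b, c)
            best = min(best, np.linalg.norm(p - cp))
        out[i] = best
    return out


# --- rigid least squares by grid + refine over axis-angle ------------------

def brute_force_rigid_residual(src, dst):
    """Global minimum of sum ||R src + t - dst||^2 over rotations.

    Multi-start Nelder-Mead over the rotation vector; the optimal
    translation for a given rotation follows from the centroids.
    Returns (residual, rotation_matrix).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)

    def objective(rv):
        rot = Rotation.from_rotvec(rv).as_matrix()
        t = dst.mean(axis=0) - rot @ src.mean(axis=0)
        return float(((src @ rot.T + t - dst) ** 2).sum())

    best = None
    grid = np.array([-2.2, 0.0, 2.2])
    for x in grid:
        for y in grid:
            for z in grid:
                res = minimize(objective, np.array([x, y, z]),
                               method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14,
                                        "maxiter": 5000, "maxfev": 5000})
                if best is None or res.fun < best.fun:
                    best = res
    rot = Rotation.from_rotvec(best.x).as_matrix()
    return best.fun, rot


# --- two-way ANOVA variance components for ICC(A,k) ------------------------

def icc_a_k_oracle(m):
    """ICC(A,k) from explicit sums of squares (independent coding)."""
    m = np.asarray(m, float)
    n, k = m.shape
    total_mean = m.sum() / (n * k)
    ss_total = ((m - total_mean) ** 2).sum()
    ss_rows = sum(k * (m[i].mean() - total_mean) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - total_mean) ** 2 for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)
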