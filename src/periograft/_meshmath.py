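"""Internal exact-geometry kernels: closest point on a triangle mesh and
ray/triangle intersection, accelerated with a k-d tree over face centroids.

Kept dependency-light on purpose: only numpy + scipy.spatial.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``tri[i]`` to ``points[i]`` (paired, (N,3)
    points against (N,3,3) triangles). Ericson's region test, vectorized."""
    p = np.asarray(points, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
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

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class MeshDistanceQuery:
    """Approximate-exact nearest-surface query: exact point-to-triangle
    distance over the k nearest faces by centroid (faces from voxel
    isosurfaces are nearly uniform in size, so small k suffices)."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 24):
        self.tri = np.asarray(vertices, dtype=float)[np.asarray(faces)]
        self.centroids = self.tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(self.centroids))

    def closest(self, points: np.ndarray):
        """Returns (closest_points, distances, face_indices)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self.tree.query(pts, k=self.k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        flat_pts = np.repeat(pts, k, axis=0)
        flat_tri = self.tri[idx.ravel()]
        cand = closest_point_on_triangles(flat_pts, flat_tri).reshape(n, k, 3)
        d = np.linalg.norm(cand - pts[:, None, :], axis=2)
        best = d.argmin(axis=1)
        rows = np.arange(n)
        return cand[rows, best], d[rows, best], idx[rows, best]


def ray_hits(
    vertices: np.ndarray,
    faces: np.ndarray,
    origins: np.ndarray,
    directions: np.ndarray,
    eps: float = 1e-9,
):
    """All ray/triangle hits (Moeller-Trumbore), brute force over faces.

    Returns (ray_index, face_index, t) arrays with t the signed distance
    along the (unit) direction, t > eps only.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    e1 = b - a
    e2 = c - a
    origins = np.atleast_2d(origins)
    directions = np.atleast_2d(directions)

    ray_idx, face_idx, ts = [], [], []
    for r, (o, d) in enumerate(zip(origins, directions)):
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > eps
        inv = np.zeros_like(det)
        inv[ok] = 1.0 / det[ok]
        tvec = o - a
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        uu = np.einsum("j,ij->i", d, qvec) * inv
        t = np.einsum("ij,ij->i", e2, qvec) * inv
        hit = ok & (u >= -eps) & (uu >= -eps) & (u + uu <= 1 + eps) & (t > eps)
        hits = np.flatnonzero(hit)
        ray_idx.extend([r] * len(hits))
        face_idx.extend(hits.tolist())
        ts.extend(t[hits].tolist())
    return np.asarray(ray_idx, dtype=int), np.asarray(face_idx, dtype=int), np.asarray(ts)


def first_hit_distances(vertices, faces, origins, directions, eps: float = 1e-9):
    """Distance to the first hit per ray (nan for misses)."""
    ri, _, ts = ray_hits(vertices, faces, origins, directions, eps)
    out = np.full(len(np.atleast_2d(origins)), np.nan)
    for r, t in zip(ri, ts):
        if np.isnan(out[r]) or t < out[r]:
            out[r] = t
    return out
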