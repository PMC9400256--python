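"""Exact nearest point on a triangle mesh for batches of query points.

Candidate triangles come from a k-d tree over triangle centroids; the exact
closest point on each candidate triangle is found with the standard
barycentric-region (Voronoi region) projection. The candidate set is grown
until the best exact distance is provably optimal: any triangle whose centroid
is farther than ``d_best + r_max`` (``r_max`` = largest centroid-to-vertex
radius in the mesh) cannot beat the current best.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyMeshError

__all__ = ["MeshProximity", "closest_point_on_triangles"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i (vectorized, Ericson's algorithm).

    ``points``: (n, 3); ``triangles``: (n, 3, 3). Returns (n, 3).
    """
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    p = points
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
    denom = d1[m] - d3[m]
    v = np.where(denom > 0, d1[m] / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = a[m] + v[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    w = np.where(denom > 0, d2[m] / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = a[m] + w[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    num = d4[m] - d3[m]
    denom = num + (d5[m] - d6[m])
    w = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = b[m] + w[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(np.abs(denom) > 1e-300, denom, 1.0)
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class MeshProximity:
    """Nearest-point queries against a fixed triangle mesh."""

    def __init__(self, mesh):
        if len(mesh.faces) == 0:
            raise EmptyMeshError("cannot build proximity structure on an empty mesh")
        self._triangles = np.asarray(mesh.triangles, dtype=float)
        self._centroids = self._triangles.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # largest centroid->vertex distance bounds how much a centroid distance
        # can overestimate the true triangle distance
        self._r_max = float(
            np.linalg.norm(self._triangles - self._centroids[:, None, :], axis=2).max()
        )
        fn = np.cross(
            self._triangles[:, 1] - self._triangles[:, 0],
            self._triangles[:, 2] - self._triangles[:, 0],
        )
        norm = np.linalg.norm(fn, axis=1)
        norm[norm == 0] = 1.0
        self._face_normals = fn / norm[:, None]
        self._n_faces = len(self._triangles)

    @property
    def face_normals(self) -> np.ndarray:
        return self._face_normals

    def query(self, points: np.ndarray, k0: int = 16):
        """Return (closest_points, distances, face_indices) for each query point."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        n = len(points)
        best_pts = np.zeros((n, 3))
        best_d = np.full(n, np.inf)
        best_f = np.zeros(n, dtype=np.int64)

        pending = np.arange(n)
        k = min(k0, self._n_faces)
        while len(pending):
            d_cand, f_cand = self._tree.query(points[pending], k=k)
            d_cand = np.atleast_2d(d_cand)
            f_cand = np.atleast_2d(f_cand)
            m = f_cand.shape[1]
            flat_f = f_cand.ravel()
            flat_p = np.repeat(points[pending], m, axis=0)
            cp = closest_point_on_triangles(flat_p, self._triangles[flat_f])
            d = np.linalg.norm(cp - flat_p, axis=1).reshape(len(pending), m)
            j = np.argmin(d, axis=1)
            rows = np.arange(len(pending))
            best_d[pending] = d[rows, j]
            best_f[pending] = f_cand[rows, j]
            best_pts[pending] = cp.reshape(len(pending), m, 3)[rows, j]
            if k >= self._n_faces:
                break
            # certified when no unexplored centroid can contain a closer point
            kth = d_cand[:, -1]
            uncertain = best_d[pending] > kth - self._r_max
            pending = pending[uncertain]
            k = min(k * 4, self._n_faces)
        return best_pts, best_d, best_f

    def signed_distance(self, points: np.ndarray):
        """Distances signed by the foot triangle's normal (positive = outside)."""
        cp, d, f = self.query(points)
        seg = np.asarray(points, dtype=float).reshape(-1, 3) - cp
        sign = np.sign(np.einsum("ij,ij->i", seg, self._face_normals[f]))
        sign[sign == 0] = 1.0
        return cp, d * sign, f
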