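"""Exact nearest-point queries from points to a triangle mesh.

Deviation analysis needs, for every sample point on a reference surface, the
exact closest point on a second surface. Queries combine a k-d tree over
triangle centroids (candidate pruning) with an exact, vectorized
point-to-triangle projection; a conservative ball-query fallback guarantees
exactness whenever the k nearest centroids cannot certify the result.
Ties are resolved toward the lowest triangle index, so results are
deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "MeshDistance"]


def closest_point_on_triangles(points, tri_a, tri_b, tri_c):
    """Closest point on each triangle ``(a, b, c)`` to each query point.

    All arguments are (n, 3) arrays; row i pairs point i with triangle i.
    Implements the standard barycentric region classification (vertex, edge,
    or face region) and is exact up to floating point.
    """
    p = np.asarray(points, dtype=float)
    a = np.asarray(tri_a, dtype=float)
    b = np.asarray(tri_b, dtype=float)
    c = np.asarray(tri_c, dtype=float)

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

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), b)
    settle((d6 >= 0) & (d5 <= d6), c)

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
        w_ac = d2 / (d2 - d6)
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        settle(
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            b + w_bc[:, None] * (c - b),
        )
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        inner = a + v[:, None] * ab + w[:, None] * ac
    # Remaining rows are in the face-interior region; degenerate (zero-area)
    # triangles fall back to vertex a, already settled above by the masks.
    inner = np.where(np.isfinite(inner), inner, a)
    out[~done] = inner[~done]
    return out


class MeshDistance:
    """Reusable exact closest-point query structure for one mesh."""

    def __init__(self, mesh, leafsize: int = 16):
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        if len(self.triangles) == 0:
            raise ValueError("mesh has no faces")
        self.centroids = self.triangles.mean(axis=1)
        # max centroid-to-vertex distance bounds how far a triangle's surface
        # can extend beyond its centroid — used for the exactness certificate
        self._radius = float(
            np.sqrt(
                ((self.triangles - self.centroids[:, None, :]) ** 2)
                .sum(axis=2)
                .max()
            )
        )
        self.tree = cKDTree(self.centroids, leafsize=leafsize)

    def query(self, points, k: int = 12):
        """Return ``(distances, closest_points, triangle_ids)``.

        ``k`` candidate triangles per point are screened first; any point
        whose k-th centroid distance cannot certify the minimum is re-run
        against every triangle whose centroid lies within
        ``best + max_triangle_radius``.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(pts)
        k_eff = min(k, len(self.centroids))
        cdist, cidx = self.tree.query(pts, k=k_eff)
        cdist = np.atleast_2d(cdist.reshape(n, k_eff))
        cidx = np.atleast_2d(cidx.reshape(n, k_eff))

        flat_pts = np.repeat(pts, k_eff, axis=0)
        flat_tid = cidx.ravel()
        tris = self.triangles[flat_tid]
        cp = closest_point_on_triangles(flat_pts, tris[:, 0], tris[:, 1], tris[:, 2])
        d = np.linalg.norm(cp - flat_pts, axis=1).reshape(n, k_eff)

        # lowest-triangle-index tie-break within floating-point-equal minima
        order = np.lexsort((flat_tid.reshape(n, k_eff), d), axis=-1)
        best_col = order[:, 0]
        rows = np.arange(n)
        best_d = d[rows, best_col]
        best_tid = cidx[rows, best_col]
        best_cp = cp.reshape(n, k_eff, 3)[rows, best_col]

        if k_eff < len(self.centroids):
            # exactness certificate: the k-th centroid must lie beyond any
            # centroid whose triangle could still undercut the current best
            uncertain = cdist[:, -1] < best_d + self._radius
            for i in np.flatnonzero(uncertain):
                ids = np.asarray(
                    self.tree.query_ball_point(pts[i], best_d[i] + self._radius)
                )
                if len(ids) == 0:
                    continue
                tris_i = self.triangles[ids]
                cp_i = closest_point_on_triangles(
                    np.broadcast_to(pts[i], (len(ids), 3)),
                    tris_i[:, 0],
                    tris_i[:, 1],
                    tris_i[:, 2],
                )
                d_i = np.linalg.norm(cp_i - pts[i], axis=1)
                j = np.lexsort((ids, d_i))[0]
                if d_i[j] < best_d[i] or (
                    d_i[j] == best_d[i] and ids[j] < best_tid[i]
                ):
                    best_d[i] = d_i[j]
                    best_tid[i] = ids[j]
                    best_cp[i] = cp_i[j]
        return best_d, best_cp, best_tid
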