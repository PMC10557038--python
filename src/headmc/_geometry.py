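"""Small exact-geometry helpers shared by surface sampling and placement."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "SurfaceLocator"]


def closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest point to ``p`` (3,) on each triangle of ``tri`` (T, 3, 3).

    Vectorized region-based projection (Ericson); returns (points (T,3),
    squared distances (T,)).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)                       # vertex a
    out[m] = a[m]; done |= m
    m = (d3 >= 0) & (d4 <= d3) & ~done              # vertex b
    out[m] = b[m]; done |= m
    m = (d6 >= 0) & (d5 <= d6) & ~done              # vertex c
    out[m] = c[m]; done |= m

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0) & ~done   # edge ab
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    out[m] = a[m] + v[m, None] * ab[m]; done |= m

    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0) & ~done   # edge ac
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0)
    out[m] = a[m] + w[m, None] * ac[m]; done |= m

    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0) & ~done  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m]); done |= m

    m = ~done                                        # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    d2o = np.einsum("ij,ij->i", out - p, out - p)
    return out, d2o


class SurfaceLocator:
    """Nearest point / face queries on a triangle surface.

    A KD-tree over face centroids prefilters candidates; exact
    point-triangle projection picks the winner among ``k`` candidates.
    """

    def __init__(self, nodes: np.ndarray, faces: np.ndarray, k: int = 48):
        self.nodes = np.asarray(nodes, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.nodes[self.faces]
        self.k = min(k, len(faces))
        self._tree = cKDTree(self.tri.mean(axis=1))

    def closest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points (Q,3), distances (Q,), face indices (Q,))."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(pts, k=self.k)
        cand = np.atleast_2d(cand)
        out = np.empty_like(pts)
        dist = np.empty(len(pts))
        fidx = np.empty(len(pts), dtype=np.int64)
        for i, p in enumerate(pts):
            cp, d2 = closest_point_on_triangles(p, self.tri[cand[i]])
            j = int(np.argmin(d2))
            out[i] = cp[j]
            dist[i] = np.sqrt(d2[j])
            fidx[i] = cand[i][j]
        return out, dist, fidx
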