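"""Low-level surface queries: exact closest point on a triangle mesh,
generalized winding numbers for inside/outside classification, and
parity-fill voxelization of watertight surfaces.

These kernels back the deviation analysis, ICP correspondence search and
phantom voxelization.  Candidate triangles are pruned with a cKDTree over
triangle centroids; ``exact=True`` widens the search to every triangle
whose centroid ball could still contain the nearest point, which makes the
result identical to a brute-force all-triangle scan.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.spatial import cKDTree


# ---------------------------------------------------------------------------
# closest point on triangle (Eberly's region decomposition)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _closest_on_triangle(p, a, b, c):
    """Closest point to ``p`` on triangle ``abc`` and its squared distance."""
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = ab[0] * ap[0] + ab[1] * ap[1] + ab[2] * ap[2]
    d2 = ac[0] * ap[0] + ac[1] * ap[1] + ac[2] * ap[2]
    if d1 <= 0.0 and d2 <= 0.0:
        q = a
        dq = p - q
        return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]

    bp = p - b
    d3 = ab[0] * bp[0] + ab[1] * bp[1] + ab[2] * bp[2]
    d4 = ac[0] * bp[0] + ac[1] * bp[1] + ac[2] * bp[2]
    if d3 >= 0.0 and d4 <= d3:
        q = b
        dq = p - q
        return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]

    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        q = a + v * ab
        dq = p - q
        return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]

    cp = p - c
    d5 = ab[0] * cp[0] + ab[1] * cp[1] + ab[2] * cp[2]
    d6 = ac[0] * cp[0] + ac[1] * cp[1] + ac[2] * cp[2]
    if d6 >= 0.0 and d5 <= d6:
        q = c
        dq = p - q
        return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]

    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        q = a + w * ac
        dq = p - q
        return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]

    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        q = b + w * (c - b)
        dq = p - q
        return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]

    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    q = a + v * ab + w * ac
    dq = p - q
    return q, dq[0] * dq[0] + dq[1] * dq[1] + dq[2] * dq[2]


@njit(cache=True)
def _closest_over_csr(points, tris, indices, indptr):
    """For each point, exact closest point over its CSR candidate list."""
    n = points.shape[0]
    dist = np.empty(n)
    closest = np.empty((n, 3))
    face = np.empty(n, dtype=np.int64)
    for i in range(n):
        p = points[i]
        best = np.inf
        bq = p
        bf = -1
        for j in range(indptr[i], indptr[i + 1]):
            t = indices[j]
            q, d2 = _closest_on_triangle(p, tris[t, 0], tris[t, 1], tris[t, 2])
            if d2 < best:
                best = d2
                bq = q
                bf = t
        dist[i] = np.sqrt(best)
        closest[i] = bq
        face[i] = bf
    return dist, closest, face


@njit(cache=True)
def _closest_all(points, tris):
    """Brute-force closest point over every triangle (oracle path)."""
    n = points.shape[0]
    dist = np.empty(n)
    closest = np.empty((n, 3))
    face = np.empty(n, dtype=np.int64)
    for i in range(n):
        p = points[i]
        best = np.inf
        bq = p
        bf = -1
        for t in range(tris.shape[0]):
            q, d2 = _closest_on_triangle(p, tris[t, 0], tris[t, 1], tris[t, 2])
            if d2 < best:
                best = d2
                bq = q
                bf = t
        dist[i] = np.sqrt(best)
        closest[i] = bq
        face[i] = bf
    return dist, closest, face


# ---------------------------------------------------------------------------
# generalized winding number
# ---------------------------------------------------------------------------


@njit(cache=True)
def _winding_numbers(points, tris):
    """Generalized winding number of each point w.r.t. a closed surface.

    Uses the van Oosterom–Strackee solid-angle formula per triangle;
    values near 1 are inside, near 0 outside.
    """
    n = points.shape[0]
    m = tris.shape[0]
    w = np.zeros(n)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        total = 0.0
        for t in range(m):
            ax = tris[t, 0, 0] - px
            ay = tris[t, 0, 1] - py
            az = tris[t, 0, 2] - pz
            bx = tris[t, 1, 0] - px
            by = tris[t, 1, 1] - py
            bz = tris[t, 1, 2] - pz
            cx = tris[t, 2, 0] - px
            cy = tris[t, 2, 1] - py
            cz = tris[t, 2, 2] - pz
            la = np.sqrt(ax * ax + ay * ay + az * az)
            lb = np.sqrt(bx * bx + by * by + bz * bz)
            lc = np.sqrt(cx * cx + cy * cy + cz * cz)
            det = (
                ax * (by * cz - bz * cy)
                - ay * (bx * cz - bz * cx)
                + az * (bx * cy - by * cx)
            )
            denom = (
                la * lb * lc
                + (ax * bx + ay * by + az * bz) * lc
                + (bx * cx + by * cy + bz * cz) * la
                + (cx * ax + cy * ay + cz * az) * lb
            )
            total += np.arctan2(det, denom)
        w[i] = total / (2.0 * np.pi)
    return w


# ---------------------------------------------------------------------------
# voxelization by z-column crossing parity
# ---------------------------------------------------------------------------


@njit(cache=True)
def _count_crossings(tris, xs, ys):
    nx = xs.shape[0]
    ny = ys.shape[0]
    counts = np.zeros(nx * ny, dtype=np.int64)
    for t in range(tris.shape[0]):
        x0, y0 = tris[t, 0, 0], tris[t, 0, 1]
        x1, y1 = tris[t, 1, 0], tris[t, 1, 1]
        x2, y2 = tris[t, 2, 0], tris[t, 2, 1]
        det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if det == 0.0:
            continue
        xmin = min(x0, min(x1, x2))
        xmax = max(x0, max(x1, x2))
        ymin = min(y0, min(y1, y2))
        ymax = max(y0, max(y1, y2))
        i0 = np.searchsorted(xs, xmin)
        i1 = np.searchsorted(xs, xmax, side="right")
        j0 = np.searchsorted(ys, ymin)
        j1 = np.searchsorted(ys, ymax, side="right")
        for i in range(i0, i1):
            for j in range(j0, j1):
                u = ((xs[i] - x0) * (y2 - y0) - (x2 - x0) * (ys[j] - y0)) / det
                v = ((x1 - x0) * (ys[j] - y0) - (xs[i] - x0) * (y1 - y0)) / det
                if u >= 0.0 and v >= 0.0 and (u + v) <= 1.0:
                    counts[i * ny + j] += 1
    return counts


@njit(cache=True)
def _fill_crossings(tris, xs, ys, offsets):
    ny = ys.shape[0]
    zvals = np.empty(offsets[-1])
    cursor = offsets[:-1].copy()
    for t in range(tris.shape[0]):
        x0, y0, z0 = tris[t, 0, 0], tris[t, 0, 1], tris[t, 0, 2]
        x1, y1, z1 = tris[t, 1, 0], tris[t, 1, 1], tris[t, 1, 2]
        x2, y2, z2 = tris[t, 2, 0], tris[t, 2, 1], tris[t, 2, 2]
        det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if det == 0.0:
            continue
        xmin = min(x0, min(x1, x2))
        xmax = max(x0, max(x1, x2))
        ymin = min(y0, min(y1, y2))
        ymax = max(y0, max(y1, y2))
        i0 = np.searchsorted(xs, xmin)
        i1 = np.searchsorted(xs, xmax, side="right")
        j0 = np.searchsorted(ys, ymin)
        j1 = np.searchsorted(ys, ymax, side="right")
        for i in range(i0, i1):
            for j in range(j0, j1):
                u = ((xs[i] - x0) * (y2 - y0) - (x2 - x0) * (ys[j] - y0)) / det
                v = ((x1 - x0) * (ys[j] - y0) - (xs[i] - x0) * (y1 - y0)) / det
                if u >= 0.0 and v >= 0.0 and (u + v) <= 1.0:
                    col = i * ny + j
                    zvals[cursor[col]] = z0 + u * (z1 - z0) + v * (z2 - z0)
                    cursor[col] += 1
    return zvals


@njit(cache=True)
def _parity_mask(zvals, offsets, zs, nx, ny):
    nz = zs.shape[0]
    mask = np.zeros((nx, ny, nz), dtype=np.bool_)
    bad = 0
    z0 = zs[0]
    dz = zs[1] - zs[0] if nz > 1 else 1.0
    for col in range(nx * ny):
        s, e = offsets[col], offsets[col + 1]
        ncross = e - s
        if ncross == 0:
            continue
        if ncross % 2 == 1:
            bad += 1
            continue
        seg = np.sort(zvals[s:e])
        i = col // ny
        j = col % ny
        for k in range(0, ncross, 2):
            lo = seg[k]
            hi = seg[k + 1]
            k0 = int(np.ceil((lo - z0) / dz))
            k1 = int(np.floor((hi - z0) / dz))
            if k0 < 0:
                k0 = 0
            if k1 > nz - 1:
                k1 = nz - 1
            for kk in range(k0, k1 + 1):
                mask[i, j, kk] = True
    return mask, bad


def parity_fill(
    triangles: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Boolean inside-mask on the grid ``xs × ys × zs`` for a watertight
    triangle set, by even–odd z-column crossing parity.

    Returns the mask and the number of degenerate columns (odd crossing
    count; callers jitter the grid slightly to avoid them).
    """
    tris = np.ascontiguousarray(triangles, dtype=np.float64)
    counts = _count_crossings(tris, xs, ys)
    offsets = np.zeros(len(counts) + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    zvals = _fill_crossings(tris, xs, ys, offsets)
    mask, bad = _parity_mask(zvals, offsets, zs, len(xs), len(ys))
    return mask, int(bad)


# ---------------------------------------------------------------------------
# surface index
# ---------------------------------------------------------------------------


class SurfaceIndex:
    """Spatial index over a triangle mesh for closest-point, signed
    distance and containment queries.

    ``k`` nearest triangle centroids bound the search; in exact mode the
    candidate set is widened with a ball query of radius
    ``upper_bound + max_triangle_radius`` so no nearer triangle can be
    missed, making results equal to a full scan.
    """

    def __init__(self, mesh) -> None:
        self.mesh = mesh
        self.triangles = np.ascontiguousarray(mesh.triangles, dtype=np.float64)
        self.centroids = self.triangles.mean(axis=1)
        self._radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self._rmax = float(self._radii.max()) if len(self._radii) else 0.0
        self._tree = cKDTree(self.centroids)
        self._face_normals: np.ndarray | None = None

    @property
    def face_normals(self) -> np.ndarray:
        """Unit face normals in winding order (lazy)."""
        if self._face_normals is None:
            t = self.triangles
            n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
            lengths = np.linalg.norm(n, axis=1)
            lengths[lengths == 0] = 1.0
            self._face_normals = n / lengths[:, None]
        return self._face_normals

    def closest(
        self, points: np.ndarray, k: int = 8, exact: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unsigned distance, closest surface point, and face index for
        each query point."""
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        m = len(self.triangles)
        if m <= max(k, 32):
            return _closest_all(points, self.triangles)
        k = min(k, m)
        _, idx = self._tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        indptr = np.arange(0, (len(points) + 1) * k, k, dtype=np.int64)
        dist, closest, face = _closest_over_csr(
            points, self.triangles, idx.ravel().astype(np.int64), indptr
        )
        if exact:
            radii = dist + self._rmax + 1e-12
            lists = self._tree.query_ball_point(points, radii)
            indices = np.concatenate(
                [np.asarray(l, dtype=np.int64) for l in lists]
            )
            indptr = np.zeros(len(points) + 1, dtype=np.int64)
            np.cumsum([len(l) for l in lists], out=indptr[1:])
            dist, closest, face = _closest_over_csr(
                points, self.triangles, indices, indptr
            )
        return dist, closest, face

    def winding(self, points: np.ndarray) -> np.ndarray:
        points = np.ascontiguousarray(np.atleast_2d(points), dtype=np.float64)
        return _winding_numbers(points, self.triangles)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inside test by generalized winding number > 1/2."""
        return self.winding(points) > 0.5


def warm_up() -> None:
    """Trigger numba compilation on a tiny input (optional convenience)."""
    tri = np.array([[[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]])
    pts = np.array([[0.2, 0.2, 1.0]])
    _closest_all(pts, tri)
    _winding_numbers(pts, tri)
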