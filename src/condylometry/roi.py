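"""Condylar region-of-interest extraction.

The condylar unit is delimited from the mandibular model by a single
inferior cut: the plane through the sigmoid-notch point Sg, perpendicular
to the Sg–Li direction (Li = external lingula projection).  The side of
the plane the normal points to — from Li toward and past Sg — is the
condylar side.  Clipping splits crossing triangles exactly at the plane
and caps the cut loop(s) by ear clipping so the result stays watertight
and its volume well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from .core import LandmarkSet, MeshError, TriangleMesh, weld_vertices

__all__ = ["CutPlane", "condylar_cut_plane", "clip_and_cap", "extract_condyle"]


@dataclass(frozen=True)
class CutPlane:
    """Oriented plane: ``point`` on the plane, unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, dtype=np.float64).reshape(3)
        n = np.asarray(self.normal, dtype=np.float64).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("plane normal is zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (points - self.point) @ self.normal


def condylar_cut_plane(Sg: np.ndarray, Li: np.ndarray) -> CutPlane:
    """Plane through Sg perpendicular to the Sg–Li line.

    The unit normal points from Li toward Sg, so the condylar head lies in
    the positive half-space.
    """
    Sg = np.asarray(Sg, dtype=np.float64)
    Li = np.asarray(Li, dtype=np.float64)
    d = Sg - Li
    if np.linalg.norm(d) == 0:
        raise ValueError("Sg and Li coincide; cut plane undefined")
    return CutPlane(point=Sg, normal=d)


# ---------------------------------------------------------------------------
# cap triangulation
# ---------------------------------------------------------------------------


def _boundary_loops(faces: np.ndarray) -> list[list[int]]:
    """Boundary loops of an oriented open surface, each traversed in the
    orientation induced by the faces (edge a→b appears once)."""
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    key = edges.min(axis=1).astype(np.int64) * (faces.max() + 1) + edges.max(axis=1)
    _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    boundary = edges[counts[inverse] == 1]
    succ = {int(a): int(b) for a, b in boundary}
    loops: list[list[int]] = []
    while succ:
        start, nxt = next(iter(succ.items()))
        loop = [start]
        del succ[start]
        while nxt != start:
            loop.append(nxt)
            follower = succ.pop(nxt, None)
            if follower is None:
                raise MeshError("open boundary chain; cannot cap cut loop")
            nxt = follower
        loops.append(loop)
    return loops


def _ear_clip(poly: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple 2D polygon (indices into ``poly``) respecting
    its winding, by ear clipping with a numerical fallback."""
    n = len(poly)
    if n < 3:
        return []
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    orient = 1.0 if area2 >= 0 else -1.0
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    scale = max(np.ptp(poly, axis=0).max(), 1e-12)
    eps = 1e-12 * scale * scale

    def cross(a, b, c):
        return (poly[b, 0] - poly[a, 0]) * (poly[c, 1] - poly[a, 1]) - (
            poly[c, 0] - poly[a, 0]
        ) * (poly[b, 1] - poly[a, 1])

    def contains(a, b, c, p):
        d1 = cross(a, b, p) * orient
        d2 = cross(b, c, p) * orient
        d3 = cross(c, a, p) * orient
        return d1 > -eps and d2 > -eps and d3 > -eps

    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 4 * n * n:
            raise MeshError("cap triangulation failed (self-intersecting loop?)")
        m = len(idx)
        best_fallback = None
        best_cross = -np.inf
        clipped = False
        for k in range(m):
            a, b, c = idx[k - 1], idx[k], idx[(k + 1) % m]
            cr = cross(a, b, c) * orient
            if cr > best_cross:
                best_cross = cr
                best_fallback = k
            if cr <= eps:
                continue
            if any(
                contains(a, b, c, p)
                for p in idx
                if p not in (a, b, c)
            ):
                continue
            tris.append((a, b, c))
            del idx[k]
            clipped = True
            break
        if not clipped:
            # numerically degenerate loop: clip the most convex vertex
            k = best_fallback
            a, b, c = idx[k - 1], idx[k], idx[(k + 1) % m]
            if best_cross > -eps * 1e3:
                tris.append((a, b, c))
            del idx[k]
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def clip_and_cap(
    mesh: TriangleMesh, plane: CutPlane, keep: str = "positive"
) -> TriangleMesh:
    """Clip a watertight mesh by a plane and cap the cut.

    Triangles on the kept side are retained, crossing triangles are split
    exactly at the plane, and each planar boundary loop is triangulated
    (ear clipping) with the winding that keeps the output consistently
    outward, hence watertight.  A plane that misses the mesh returns the
    whole mesh or an empty mesh depending on the side.
    """
    if keep not in ("positive", "negative"):
        raise ValueError("keep must be 'positive' or 'negative'")
    if not mesh.is_watertight():
        raise MeshError("clip requires a watertight input mesh")
    normal = plane.normal if keep == "positive" else -plane.normal

    sd = (mesh.vertices - plane.point) @ normal
    if sd.min() >= 0:
        return mesh.copy()
    if sd.max() <= 0:
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

    sliced = slice_mesh_plane(
        mesh.as_trimesh(), plane_normal=normal, plane_origin=plane.point
    )
    if len(sliced.faces) == 0:
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    open_mesh = weld_vertices(
        np.asarray(sliced.vertices), np.asarray(sliced.faces), tolerance=1e-9
    )

    loops = _boundary_loops(open_mesh.faces)
    # 2D basis in the cut plane
    n = normal
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)

    cap_faces: list[tuple[int, int, int]] = []
    for loop in loops:
        # the cap shares each boundary edge in the opposite direction,
        # so triangulate the reversed loop to keep winding consistent
        rev = loop[::-1]
        pts = open_mesh.vertices[rev]
        poly = np.column_stack([pts @ e1, pts @ e2])
        for a, b, c in _ear_clip(poly):
            cap_faces.append((rev[a], rev[b], rev[c]))

    faces = np.vstack([open_mesh.faces, np.array(cap_faces, dtype=np.int64)])
    keep_faces = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    result = TriangleMesh(open_mesh.vertices, faces[keep_faces])
    if not result.is_watertight():
        raise MeshError("cap triangulation produced a non-watertight result")
    return result


def extract_condyle(
    mandible: TriangleMesh, landmarks: LandmarkSet, side: str
) -> TriangleMesh:
    """Cut the condylar unit of one side from a mandibular model.

    Uses the Sg/Li landmarks of ``side`` ('L' or 'R') to build the cut
    plane, clips keeping the condylar (positive) half-space, and returns
    the connected component containing that side's condylar head — the
    component nearest the side's Sg landmark (both condyles can survive a
    near-horizontal cut; proximity to Sg disambiguates them).
    """
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    sg_name, li_name = f"Sg_{side}", f"Li_{side}"
    if sg_name not in landmarks or li_name not in landmarks:
        raise ValueError(f"landmarks {sg_name}/{li_name} missing")
    plane = condylar_cut_plane(landmarks[sg_name], landmarks[li_name])
    clipped = clip_and_cap(mandible, plane, keep="positive")
    if clipped.n_faces == 0:
        raise MeshError("plane excludes condyle: empty result")
    tm = trimesh.Trimesh(
        vertices=clipped.vertices, faces=clipped.faces, process=False
    )
    parts = tm.split(only_watertight=False)
    if len(parts) <= 1:
        return clipped
    sg = landmarks[sg_name]
    dists = [
        float(np.linalg.norm(np.asarray(p.vertices) - sg, axis=1).min())
        for p in parts
    ]
    best = parts[int(np.argmin(dists))]
    return TriangleMesh(np.asarray(best.vertices), np.asarray(best.faces))
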