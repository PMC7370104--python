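"""Core geometry containers shared by every stage of the pipeline.

Units are millimetres throughout, matching the scale of CBCT-derived
surface models of the mandible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import trimesh

#: Landmarks used for the four-point preliminary registration: the
#: geometric centres of the left/right mental foramina and the left/right
#: lingulae on the inner ramus surface.
REGISTRATION_LANDMARKS = (
    "mental_foramen_L",
    "mental_foramen_R",
    "lingula_L",
    "lingula_R",
)

#: Landmarks delimiting the condylar unit: sigmoid-notch point (Sg) and the
#: external projection of the lingula (Li), per side.
CONDYLE_LANDMARKS = ("Sg_L", "Sg_R", "Li_L", "Li_R")

KNOWN_LANDMARKS = REGISTRATION_LANDMARKS + CONDYLE_LANDMARKS

#: Vertex weld tolerance applied when indexing STL triangle soup (mm).
#: Far below the 0.3 mm voxel scale, so geometry is preserved.
WELD_TOLERANCE = 1e-6


class MeshError(ValueError):
    """Raised for topologically or numerically invalid mesh input."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Vertex indices of each triangle, counter-clockwise when viewed
        from outside for a consistently wound surface.
    scalars : (n,) float array, optional
        Per-vertex scalar channel in mm, used to carry signed deviations
        for colour-coded maps.
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {self.faces.shape}")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise MeshError(
                    f"{int(degenerate.sum())} faces repeat a vertex (degenerate)"
                )
        if self.scalars is not None:
            self.scalars = np.ascontiguousarray(self.scalars, dtype=np.float64)
            if self.scalars.shape != (len(self.vertices),):
                raise MeshError(
                    "scalar channel length must equal vertex count "
                    f"({self.scalars.shape} vs {len(self.vertices)})"
                )

    # -- basic queries ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def is_watertight(self) -> bool:
        """True when every edge is shared by exactly two consistently
        wound faces — the precondition for enclosed-volume computation."""
        tm = self.as_trimesh()
        return bool(tm.is_watertight and tm.is_winding_consistent)

    def euler_characteristic(self) -> int:
        tm = self.as_trimesh()
        return int(tm.euler_number)

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        return np.asarray(self.as_trimesh().vertex_normals, dtype=np.float64)

    def edge_lengths(self) -> np.ndarray:
        tri = self.triangles
        e = np.concatenate(
            [
                tri[:, 1] - tri[:, 0],
                tri[:, 2] - tri[:, 1],
                tri[:, 0] - tri[:, 2],
            ]
        )
        return np.linalg.norm(e, axis=1)

    def with_scalars(self, scalars: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(self.vertices, self.faces, scalars)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalars is None else self.scalars.copy(),
        )


def weld_vertices(
    vertices: np.ndarray,
    faces: np.ndarray,
    tolerance: float = WELD_TOLERANCE,
) -> TriangleMesh:
    """Merge vertices closer than ``tolerance`` and drop collapsed faces.

    STL stores an unindexed triangle soup; downstream stages (volume,
    clipping, winding) need shared vertices, so coordinates are snapped to
    a ``tolerance``-pitch grid and deduplicated.
    """
    vertices = np.asarray(vertices, dtype=np.float64)
    faces = np.asarray(faces, dtype=np.int64)
    key = np.round(vertices / tolerance).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    new_vertices = vertices[first]
    new_faces = inverse[faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return TriangleMesh(new_vertices, new_faces[keep])


class LandmarkError(ValueError):
    """Raised for invalid landmark sets (unknown names, degenerate
    configurations)."""


@dataclass
class LandmarkSet:
    """Named anatomical points in mesh coordinates (mm)."""

    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            if name not in KNOWN_LANDMARKS:
                raise LandmarkError(f"unknown landmark name: {name!r}")
            p = np.asarray(p, dtype=np.float64).reshape(-1)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {name!r} is not a finite 3D point")
            clean[name] = p
        self.points = clean
        for side in ("L", "R"):
            sg, li = f"Sg_{side}", f"Li_{side}"
            if sg in clean and li in clean and np.allclose(clean[sg], clean[li]):
                raise LandmarkError(f"Sg and Li coincide on side {side}")
        reg = [clean[n] for n in REGISTRATION_LANDMARKS if n in clean]
        if len(reg) >= 3 and _collinear(np.array(reg)):
            raise LandmarkError("registration landmarks are collinear")

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def names(self) -> tuple[str, ...]:
        return tuple(self.points)

    def subset(self, names: Iterable[str]) -> "LandmarkSet":
        return LandmarkSet({n: self.points[n] for n in names if n in self.points})

    def shared_names(self, other: "LandmarkSet") -> tuple[str, ...]:
        return tuple(n for n in self.points if n in other.points)

    def as_array(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.points[n] for n in names], dtype=np.float64)

    def transformed(self, apply) -> "LandmarkSet":
        """Return a copy with ``apply`` (point-array -> point-array)
        applied to every landmark."""
        names = self.names()
        moved = apply(self.as_array(names))
        return LandmarkSet(dict(zip(names, moved)))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    """True when all points lie on one line (relative tolerance on the
    second singular value of the centred configuration)."""
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    return bool(s[1] / scale < tol)
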