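"""Reading and writing of the surface-model and landmark files the
pipeline exchanges: STL (ASCII and binary), vertex-coloured PLY for
deviation maps, and plain-text landmark tables.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import trimesh

from .core import LandmarkError, LandmarkSet, TriangleMesh, weld_vertices

__all__ = [
    "STLFormatError",
    "EmptyMeshError",
    "LandmarkParseError",
    "read_stl",
    "write_stl",
    "write_colored_mesh",
    "deviation_colors",
    "read_landmarks",
    "write_landmarks",
]


class STLFormatError(ValueError):
    """Raised when an STL file cannot be parsed."""


class EmptyMeshError(ValueError):
    """Raised when a surface file contains no triangles."""


class LandmarkParseError(ValueError):
    """Raised when a landmark file is malformed."""


_BINARY_HEADER = 84
_BINARY_RECORD = 50


def read_stl(path: str | Path, weld_tolerance: float = 1e-6) -> TriangleMesh:
    """Read an ASCII or binary STL file into an indexed mesh.

    STL stores an unindexed triangle soup; vertices within
    ``weld_tolerance`` mm of each other are merged so that downstream
    topology queries (watertightness, volume, clipping) are possible.
    Coordinates are taken as millimetres, pass-through.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) == 0:
        raise STLFormatError(f"{path}: empty file")

    is_ascii = data[:5].lower() == b"solid" and b"facet" in data[:2048]
    if not is_ascii:
        if len(data) < _BINARY_HEADER:
            raise STLFormatError(
                f"{path}: binary STL needs at least {_BINARY_HEADER} header "
                f"bytes, file has {len(data)}"
            )
        n_declared = int(np.frombuffer(data[80:84], dtype="<u4")[0])
        expected = _BINARY_HEADER + _BINARY_RECORD * n_declared
        if len(data) != expected:
            raise STLFormatError(
                f"{path}: binary STL declares {n_declared} triangles "
                f"({expected} bytes expected) but file has {len(data)} bytes"
            )
    try:
        kwargs = trimesh.exchange.stl.load_stl(_io.BytesIO(data))
    except Exception as exc:  # noqa: BLE001 - third-party parse failures
        raise STLFormatError(f"{path}: unparseable STL ({exc})") from exc

    vertices = np.asarray(kwargs["vertices"], dtype=np.float64)
    faces = np.asarray(kwargs["faces"], dtype=np.int64)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path}: STL contains no facets")
    return weld_vertices(vertices, faces, tolerance=weld_tolerance)


def _face_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.triangles
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lengths = np.linalg.norm(n, axis=1)
    lengths[lengths == 0] = 1.0
    return n / lengths[:, None]


def write_stl(
    mesh: TriangleMesh, path: str | Path, mode: str = "ascii"
) -> Path:
    """Write ``mesh`` as STL.  Facet normals are recomputed from winding.

    ASCII mode uses 9-significant-digit decimals under a fixed
    ``solid condylometry`` header so exports diff reproducibly; binary
    mode is the standard 84 + 50·n byte layout.
    """
    path = Path(path)
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write a mesh with zero faces")
    if mode == "ascii":
        normals = _face_normals(mesh)
        tri = mesh.triangles
        lines = ["solid condylometry"]
        for f in range(mesh.n_faces):
            nx, ny, nz = normals[f]
            lines.append(f"  facet normal {nx:.9g} {ny:.9g} {nz:.9g}")
            lines.append("    outer loop")
            for v in range(3):
                x, y, z = tri[f, v]
                lines.append(f"      vertex {x:.9g} {y:.9g} {z:.9g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid condylometry")
        path.write_text("\n".join(lines) + "\n")
    elif mode == "binary":
        data = trimesh.exchange.stl.export_stl(mesh.as_trimesh())
        path.write_bytes(data)
    else:
        raise ValueError(f"mode must be 'ascii' or 'binary', got {mode!r}")
    return path


def deviation_colors(
    scalars: np.ndarray, tolerance: float, clamp: float = 1.0
) -> np.ndarray:
    """Map signed deviations (mm) to the conventional banded colour scale.

    Within ``±tolerance`` the colour is green; above it ramps warm
    (yellow → red, overestimation) and below it ramps cool (cyan → blue,
    underestimation), saturating at ``±clamp``.
    Returns uint8 RGB, one row per sample.
    """
    s = np.asarray(scalars, dtype=np.float64)
    rgb = np.zeros((len(s), 3), dtype=np.float64)
    span = max(clamp - tolerance, 1e-12)
    within = np.abs(s) <= tolerance
    rgb[within] = (0.0, 170.0, 0.0)
    over = s > tolerance
    t = np.clip((s[over] - tolerance) / span, 0.0, 1.0)
    rgb[over, 0] = 255.0
    rgb[over, 1] = 255.0 * (1.0 - t)
    under = s < -tolerance
    t = np.clip((-s[under] - tolerance) / span, 0.0, 1.0)
    rgb[under, 2] = 255.0
    rgb[under, 1] = 255.0 * (1.0 - t)
    return np.round(rgb).astype(np.uint8)


def write_colored_mesh(
    mesh: TriangleMesh,
    tolerance: float,
    path: str | Path,
    clamp: float = 1.0,
) -> Path:
    """Write a vertex-coloured ASCII PLY of a deviation-annotated mesh.

    The per-vertex scalar channel (signed deviation, mm) drives the colour
    band: green inside the tolerance, warm for overestimation, cool for
    underestimation. STL cannot carry colour portably, hence PLY.
    """
    path = Path(path)
    if mesh.scalars is None:
        raise ValueError("mesh has no scalar channel to colour")
    rgb = deviation_colors(mesh.scalars, tolerance, clamp)
    tm = mesh.as_trimesh()
    tm.visual.vertex_colors = np.hstack(
        [rgb, np.full((len(rgb), 1), 255, dtype=np.uint8)]
    )
    path.write_bytes(trimesh.exchange.ply.export_ply(tm, encoding="ascii"))
    return path


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> Path:
    """Write landmarks as plain text: one ``name x y z`` record per line."""
    path = Path(path)
    lines = ["# landmark x y z (mm)"]
    for name in landmarks.names():
        x, y, z = landmarks[name]
        lines.append(f"{name} {x:.17g} {y:.17g} {z:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark text file (whitespace- or comma-separated)."""
    path = Path(path)
    points: dict[str, np.ndarray] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 4:
            raise LandmarkParseError(
                f"{path}:{lineno}: expected 'name x y z', got {raw!r}"
            )
        name = parts[0]
        if name in points:
            raise LandmarkParseError(f"{path}:{lineno}: duplicate landmark {name!r}")
        try:
            xyz = np.array([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise LandmarkParseError(
                f"{path}:{lineno}: non-numeric coordinate in {raw!r}"
            ) from exc
        points[name] = xyz
    try:
        return LandmarkSet(points)
    except LandmarkError as exc:
        raise LandmarkParseError(f"{path}: {exc}") from exc
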