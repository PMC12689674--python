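"""Mesh and rigid-geometry primitives.

Everything downstream works in millimetres on triangle surface meshes.
This module provides the three carrier types (:class:`TriMesh`,
:class:`Plane`, :class:`RigidTransform`), STL/PLY input and output, and
closed-form rigid superposition (Kabsch).

STL files carry no unit information; the convention throughout the
package is that coordinates are millimetres as stored.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "OsteoguideError",
    "ContractError",
    "FormatError",
    "DegenerateGeometryError",
    "TriMesh",
    "Plane",
    "RigidTransform",
    "read_stl",
    "write_stl",
    "write_ply_scalar",
    "kabsch_superpose",
    "apply_transform",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class OsteoguideError(Exception):
    """Base class for all package errors."""


class ContractError(OsteoguideError, ValueError):
    """A function was called with arguments violating its contract."""


class FormatError(OsteoguideError):
    """A file does not conform to its declared format."""


class DegenerateGeometryError(OsteoguideError):
    """Geometry is degenerate (collinear points, zero normal, ...)."""


# ---------------------------------------------------------------------------
# Carrier types
# ---------------------------------------------------------------------------

def _as_points(a, name: str = "points") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ContractError(f"{name} must be an (n, 3) array, got shape {a.shape}")
    return a


@dataclass
class TriMesh:
    """Triangle surface mesh: vertices (mm), faces, optional per-vertex scalar.

    The scalar channel carries derived per-vertex quantities such as the
    deviation heat map (mm).
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ContractError(f"faces must be (m, 3), got shape {self.faces.shape}")
        if len(self.vertices) < 3:
            raise ContractError("mesh needs at least 3 vertices")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ContractError("face indices out of range")
        if self.scalar is not None:
            self.scalar = np.asarray(self.scalar, dtype=float)
            if self.scalar.shape != (len(self.vertices),):
                raise ContractError("scalar must have one value per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalar is None else self.scalar.copy(),
        )

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh, scalar=None) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), scalar)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def concatenate(self, other: "TriMesh") -> "TriMesh":
        verts = np.vstack([self.vertices, other.vertices])
        faces = np.vstack([self.faces, other.faces + self.n_vertices])
        scalar = None
        if self.scalar is not None and other.scalar is not None:
            scalar = np.concatenate([self.scalar, other.scalar])
        return TriMesh(verts, faces, scalar)


@dataclass
class Plane:
    """Oriented plane: a point on it plus an outward unit normal (mm)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ContractError("plane normal must be nonzero")
        self.normal = n / norm

    def signed_distance(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d[0] if np.asarray(points).ndim == 1 else d

    def flipped(self) -> "Plane":
        return Plane(self.point.copy(), -self.normal)

    def transformed(self, t: "RigidTransform") -> "Plane":
        return Plane(t.apply(self.point), t.rotation @ self.normal)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-7):
            raise ContractError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ContractError("reflection passed as rotation (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


# ---------------------------------------------------------------------------
# STL / PLY input and output
# ---------------------------------------------------------------------------

def _dedupe_vertices(vertices: np.ndarray, faces: np.ndarray,
                     merge_tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than merge_tol (grid snap) and drop degenerate faces."""
    if merge_tol > 0:
        keys = np.round(vertices / merge_tol).astype(np.int64)
    else:
        keys = vertices
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    new_vertices = vertices[first]
    new_faces = inverse[faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[ok]


def _validate_binary_stl(path: Path) -> None:
    size = path.stat().st_size
    if size < 84:
        raise FormatError(
            f"{path}: binary STL truncated at byte {size} (header needs 84 bytes)"
        )
    with open(path, "rb") as fh:
        fh.seek(80)
        (count,) = struct.unpack("<I", fh.read(4))
    expected = 84 + 50 * count
    if size < expected:
        raise FormatError(
            f"{path}: binary STL declares {count} facets ({expected} bytes) "
            f"but file ends at byte {size}"
        )


def _looks_ascii(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if not head.lstrip().startswith(b"solid"):
        return False
    # binary files may also start with 'solid'; require a 'facet' token
    return b"facet" in head or b"endsolid" in head


def read_stl(path, merge_tol: float = 1e-6) -> TriMesh:
    """Read a binary or ASCII STL file into a :class:`TriMesh`.

    STL stores three explicit vertices per facet; vertices closer than
    ``merge_tol`` (mm) are merged so downstream operations see shared
    topology. Degenerate (zero-area after merging) faces are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not _looks_ascii(path):
        _validate_binary_stl(path)
    try:
        tm = _trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # malformed ASCII body, bad records, ...
        raise FormatError(f"{path}: cannot parse STL ({exc})") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path}: no triangles found in STL")
    vertices, faces = _dedupe_vertices(
        np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces), merge_tol
    )
    if len(vertices) < 3 or len(faces) == 0:
        raise FormatError(f"{path}: STL degenerates to fewer than 3 vertices")
    return TriMesh(vertices, faces)


def write_stl(mesh: TriMesh, path, mode: str = "binary") -> None:
    """Write ``mesh`` as STL; ``mode`` is ``'binary'`` or ``'ascii'``."""
    if mesh.n_faces == 0:
        raise ContractError("refusing to write an empty mesh")
    if mode not in ("binary", "ascii"):
        raise ContractError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    tm = mesh.to_trimesh()
    file_type = "stl" if mode == "binary" else "stl_ascii"
    data = _trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    out_mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, out_mode) as fh:
        fh.write(data)


def write_ply_scalar(mesh: TriMesh, path) -> None:
    """Write an ASCII PLY with the per-vertex scalar as a float ``quality``.

    The quality channel is what generic mesh viewers colour-map, so this
    is the heat-map export format.
    """
    if mesh.scalar is None:
        raise ContractError("mesh has no per-vertex scalar to export")
    if mesh.n_faces == 0:
        raise ContractError("refusing to write an empty mesh")
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        "property float quality",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, q in zip(mesh.vertices, mesh.scalar):
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {q:.6f}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Rigid superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(p, q) -> RigidTransform:
    """Least-squares rigid superposition of corresponding point sets.

    Returns the proper rotation R and translation t minimising
    sum_i |R p_i + t - q_i|^2 (Kabsch/Umeyama without scaling). A
    reflection solution is excluded by sign-correcting the smallest
    singular direction; anatomy must never be mirrored.
    """
    p = _as_points(p, "P")
    q = _as_points(q, "Q")
    if p.shape != q.shape:
        raise ContractError("P and Q must have the same shape")
    if len(p) < 3:
        raise DegenerateGeometryError("need at least 3 correspondences")
    p_mean = p.mean(axis=0)
    q_mean = q.mean(axis=0)
    pc = p - p_mean
    qc = q - q_mean
    scale = max(np.abs(pc).max(), 1e-30)
    # collinearity: second singular value of centred P vanishes
    sv = np.linalg.svd(pc, compute_uv=False)
    if sv[1] <= 1e-9 * scale:
        raise DegenerateGeometryError("point set is collinear; rotation underdetermined")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = q_mean - r @ p_mean
    return RigidTransform(r, t)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid transform to a TriMesh, a Plane, or an (n, 3) point array."""
    if isinstance(obj, TriMesh):
        return TriMesh(
            transform.apply(obj.vertices),
            obj.faces.copy(),
            None if obj.scalar is None else obj.scalar.copy(),
        )
    if isinstance(obj, Plane):
        return obj.transformed(transform)
    return transform.apply(obj)
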