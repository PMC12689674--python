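"""Cut-face identification and oriented osteotomy-plane fitting.

In the physical study the osteotomy surfaces were marked manually on the
segmented scans before planes were fitted. Here the marking is automated:
region growing over mesh faces whose normals agree within a planarity
tolerance finds the two planar cut caps of a segment, and an orthogonal
least-squares (total least squares) plane is fitted to each. A sidecar
label file can bypass the detection entirely.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh_core import (
    ContractError,
    DegenerateGeometryError,
    OsteoguideError,
    Plane,
    TriMesh,
)

__all__ = [
    "CutFace",
    "DetectionError",
    "detect_cut_faces",
    "fit_plane",
    "orient_outward",
    "cut_faces_from_labels",
    "write_labels_csv",
    "read_labels_csv",
]

log = logging.getLogger(__name__)

DEFAULT_PLANARITY_TOL_DEG = 5.0
DEFAULT_MIN_AREA_MM2 = 20.0


class DetectionError(OsteoguideError):
    """Automatic cut-face detection failed; provide manual labels."""


@dataclass
class CutFace:
    """A detected/labelled osteotomy surface on one segment mesh."""

    vertex_indices: np.ndarray
    role: str                       # 'proximal' | 'distal'
    fitted: Plane
    fit_rms: float

    def __post_init__(self) -> None:
        if self.role not in ("proximal", "distal"):
            raise ContractError(f"role must be proximal|distal, got {self.role!r}")
        if self.fit_rms < 0:
            raise ContractError("fit_rms must be >= 0")


def fit_plane(points) -> tuple[Plane, float]:
    """Orthogonal least-squares plane through a point cloud.

    Returns the plane through the centroid whose normal is the direction
    of smallest scatter, plus the RMS orthogonal residual. The fit is
    rotation invariant by construction. Raises
    :class:`DegenerateGeometryError` for collinear/duplicate inputs
    (two smallest scatter directions indistinguishable).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ContractError("need an (n >= 3, 3) point array")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    scale = max(np.abs(centred).max(), 1e-30)
    # singular values of the centred cloud = sqrt(n) * scatter per direction
    u_, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= 1e-12 * scale * len(pts):
        raise DegenerateGeometryError("points are collinear; plane underdetermined")
    normal = vt[2]
    rms = float(s[2] / np.sqrt(len(pts)))
    return Plane(centroid, normal), rms


def orient_outward(plane: Plane, segment_centroid, tie_axis=None) -> Plane:
    """Flip the plane normal, if needed, to point away from the segment interior.

    If the centroid lies exactly on the plane the tie is broken toward
    ``tie_axis`` (default +Z) and logged.
    """
    c = np.asarray(segment_centroid, dtype=float).reshape(3)
    d = (plane.point - c) @ plane.normal
    if d > 0:
        return plane
    if d < 0:
        return plane.flipped()
    axis = np.array([0.0, 0.0, 1.0]) if tie_axis is None else np.asarray(tie_axis, float)
    log.warning("segment centroid lies on the cut plane; tie broken toward +axis")
    return plane if plane.normal @ axis >= 0 else plane.flipped()


def _principal_axis(vertices: np.ndarray) -> np.ndarray:
    """First principal direction of the vertex cloud, sign-fixed.

    The sign is chosen so the largest-magnitude component is positive, a
    documented convention standing in for the study's (unspecified) leg
    positioning reference.
    """
    centred = vertices - vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis


def detect_cut_faces(
    mesh: TriMesh,
    planarity_tol: float = DEFAULT_PLANARITY_TOL_DEG,
    min_area: float = DEFAULT_MIN_AREA_MM2,
) -> list[CutFace]:
    """Find the two osteotomy caps of a segment mesh and fit their planes.

    Faces are grouped by region growing across mesh edges whose dihedral
    normal change stays within ``planarity_tol`` degrees; regions of
    total area >= ``min_area`` mm^2 qualify, and the two largest are
    assigned proximal (+principal-axis side) and distal. Raises
    :class:`DetectionError` when fewer than two planar regions are
    found, in which case manual labels should be supplied.
    """
    if planarity_tol <= 0:
        raise DetectionError("planarity_tol must be positive; got a degenerate tolerance")
    tm = mesh.to_trimesh()
    adjacency = tm.face_adjacency
    angles = tm.face_adjacency_angles
    n_faces = mesh.n_faces
    keep = angles < np.radians(planarity_tol)
    edges = adjacency[keep]
    graph = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
        shape=(n_faces, n_faces),
    )
    n_comp, comp = connected_components(graph, directed=False)
    areas = np.asarray(tm.area_faces)
    face_normals = np.asarray(tm.face_normals)

    regions = []
    for rid in range(n_comp):
        members = np.flatnonzero(comp == rid)
        area = areas[members].sum()
        if area < min_area:
            continue
        # coherence: a cap is globally planar, not just smoothly curved
        mean_n = np.average(face_normals[members], axis=0, weights=areas[members])
        norm = np.linalg.norm(mean_n)
        if norm < 1e-12:
            continue
        mean_n /= norm
        cosmax = np.cos(np.radians(planarity_tol))
        if np.min(face_normals[members] @ mean_n) < cosmax:
            continue
        regions.append((area, members))
    if len(regions) < 2:
        raise DetectionError(
            f"found {len(regions)} planar region(s) >= {min_area} mm^2; "
            "supply manual cut-face labels"
        )
    regions.sort(key=lambda r: r[0], reverse=True)
    picked = regions[:2]

    axis = _principal_axis(mesh.vertices)
    centroid = mesh.centroid()
    results = []
    projections = []
    for _, members in picked:
        vidx = np.unique(mesh.faces[members].ravel())
        plane, rms = fit_plane(mesh.vertices[vidx])
        plane = orient_outward(plane, centroid, tie_axis=axis)
        projections.append(float((plane.point - centroid) @ axis))
        results.append((vidx, plane, rms))
    order = np.argsort(projections)[::-1]          # proximal = +axis side
    roles = {order[0]: "proximal", order[1]: "distal"}
    faces = [
        CutFace(results[i][0], roles[i], results[i][1], results[i][2])
        for i in range(2)
    ]
    faces.sort(key=lambda f: f.role != "proximal")
    return faces


def cut_faces_from_labels(mesh: TriMesh, labels: dict[str, np.ndarray]) -> list[CutFace]:
    """Build CutFaces from pre-marked vertex labels (bypasses detection)."""
    out = []
    centroid = mesh.centroid()
    for role in ("proximal", "distal"):
        if role not in labels:
            raise ContractError(f"labels missing role {role!r}")
        vidx = np.asarray(labels[role], dtype=np.int64)
        plane, rms = fit_plane(mesh.vertices[vidx])
        out.append(CutFace(vidx, role, orient_outward(plane, centroid), rms))
    return out


def write_labels_csv(labels: dict[str, np.ndarray], path) -> None:
    """Sidecar label file: one row per labelled vertex (vertex_index, face_role)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_index", "face_role"])
        for role in ("proximal", "distal"):
            for v in np.asarray(labels[role]).ravel():
                w.writerow([int(v), role])


def read_labels_csv(path) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {"proximal": [], "distal": []}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            role = row["face_role"]
            if role not in out:
                raise ContractError(f"unknown face_role {role!r} in {path}")
            out[role].append(int(row["vertex_index"]))
    return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}
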