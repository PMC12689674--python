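"""Synthetic fibula analogs, virtual surgical plans and executed-cut simulation.

The in vitro study this package evaluates cuts plastic fibula analogs into
three segments through printed cutting guides, under a full factorial
design: three slot designs (SS standard bilateral slot, FS unilateral
flange, AS anatomical slot) x three guide heights (1, 2, 3 mm) x two
instruments (oscillating saw, kerf 0.3 mm; piezoelectric, kerf 0.45 mm)
x five replicates = 90 specimens, 270 segments, 540 osteotomy planes.

This module generates fibula-like tubular meshes, three-segment virtual
plans with closing wedges at the two joints, and "executed" cut planes
perturbed by a Gaussian shift/tilt model whose tilt can be truncated at
the groove-restriction bound arctan((slot - kerf) / height). Everything
is deterministic given a seed, so the whole downstream pipeline is
testable without any scan data.

Coordinate convention (fibula frame): right-handed, +Z proximal along
the shaft, +X vestibular (the guide-contact surface), units mm.
Segments are listed in chain order from proximal (high Z) to distal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .mesh_core import (
    ContractError,
    DegenerateGeometryError,
    Plane,
    RigidTransform,
    TriMesh,
)

__all__ = [
    "FibulaParams",
    "GuideGeometry",
    "SegmentPlan",
    "PerturbationModel",
    "StudyDesign",
    "SegmentMesh",
    "PlanValidationError",
    "SLOT_WIDTH_MM",
    "KERF_MM",
    "MIN_LINGUAL_LENGTH_MM",
    "groove_tilt_bound",
    "cross_section_profile",
    "generate_fibula_mesh",
    "make_plan",
    "perturb_plan",
    "build_segments",
    "default_perturbation",
    "guide_for_cell",
]

# Guide geometry used throughout the study: 1 mm working slot width; blade
# kerf 0.3 mm for the oscillating saw and 0.45 mm for the piezoelectric
# instrument.
SLOT_WIDTH_MM = 1.0
KERF_MM = {"saw": 0.3, "piezo": 0.45}

# A fibula segment shorter than 20 mm cannot maintain adequate periosteal
# blood flow; plans below this lingual length are rejected.
MIN_LINGUAL_LENGTH_MM = 20.0

_DESIGNS = ("SS", "FS", "AS")
_INSTRUMENTS = ("saw", "piezo")


class PlanValidationError(ContractError):
    """A virtual surgical plan violates a clinical or geometric constraint."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class FibulaParams:
    """Shape parameters of the synthetic fibula shaft.

    ``cross_section_shape`` controls how triangular the rounded-triangle
    cross-section is (0 = circle; 0.18 approximates a fibula diaphysis).
    ``curvature`` bows the shaft centreline in +Y with sagitta
    curvature * L^2 / 8 at mid-shaft.
    """

    shaft_length: float = 140.0
    cross_section_width: float = 14.0
    cross_section_shape: float = 0.18
    curvature: float = 0.0
    axial_resolution: int = 48
    circumferential_resolution: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axial_resolution < 3 or self.circumferential_resolution < 3:
            raise ContractError("resolutions must be >= 3")
        if self.shaft_length <= 0 or self.cross_section_width <= 0:
            raise ContractError("shaft_length and cross_section_width must be positive")


@dataclass
class GuideGeometry:
    """Slot geometry of one cutting guide configuration."""

    slot_width: float = SLOT_WIDTH_MM
    blade_kerf: float = KERF_MM["saw"]
    guide_height: float = 1.0
    design: str = "SS"
    instrument: str = "saw"

    def __post_init__(self) -> None:
        if self.design not in _DESIGNS:
            raise ContractError(f"design must be one of {_DESIGNS}, got {self.design!r}")
        if self.instrument not in _INSTRUMENTS:
            raise ContractError(
                f"instrument must be one of {_INSTRUMENTS}, got {self.instrument!r}"
            )
        if self.blade_kerf <= 0 or self.slot_width <= 0 or self.guide_height <= 0:
            raise ContractError("slot_width, blade_kerf, guide_height must be positive")
        if self.blade_kerf >= self.slot_width:
            raise ContractError(
                f"blade kerf {self.blade_kerf} mm cannot enter slot of width "
                f"{self.slot_width} mm"
            )


def groove_tilt_bound(g: GuideGeometry) -> float:
    """Maximum blade tilt (degrees) allowed by the slot groove.

    A blade of kerf k in a slot of width w guided over height h can tilt
    at most arctan((w - k) / h) before jamming against the slot walls.
    The unilateral flange (FS) has no second wall, so its bound is +inf.
    """
    if g.design == "FS":
        return math.inf
    return math.degrees(math.atan((g.slot_width - g.blade_kerf) / g.guide_height))


# ---------------------------------------------------------------------------
# Fibula mesh
# ---------------------------------------------------------------------------

def cross_section_profile(params: FibulaParams) -> np.ndarray:
    """Rounded-triangular cross-section polygon, CCW, (n, 2) in mm.

    The flattest side faces +X (the vestibular, guide-contact surface)
    and the X extent equals ``cross_section_width``.
    """
    n = params.circumferential_resolution
    phi = 2.0 * math.pi * np.arange(n) / n
    r = 1.0 - params.cross_section_shape * np.cos(3.0 * phi)
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    scale = params.cross_section_width / (x.max() - x.min())
    x = (x - 0.5 * (x.max() + x.min())) * scale
    y = (y - 0.5 * (y.max() + y.min())) * scale
    return np.column_stack([x, y])


def _bow(params: FibulaParams, z):
    """Centreline +Y offset of the bowed shaft at axial position z."""
    return 0.5 * params.curvature * z * (params.shaft_length - z)


def _tube_faces(n_rings: int, m: int) -> np.ndarray:
    """Faces of a closed tube of n_rings rings of m vertices plus 2 cap centres.

    Vertex layout: ring-major (ring k vertex j at index k*m + j), then the
    bottom-cap centre at n_rings*m and the top-cap centre at n_rings*m + 1.
    Rings are CCW viewed from +Z, so this winding points all normals outward.
    """
    faces = []
    for k in range(n_rings - 1):
        a = k * m + np.arange(m)
        b = k * m + (np.arange(m) + 1) % m
        c = (k + 1) * m + (np.arange(m) + 1) % m
        d = (k + 1) * m + np.arange(m)
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([a, c, d]))
    bot_c = n_rings * m
    top_c = n_rings * m + 1
    j = np.arange(m)
    jn = (j + 1) % m
    faces.append(np.column_stack([np.full(m, bot_c), jn, j]))           # -Z cap
    top = (n_rings - 1) * m
    faces.append(np.column_stack([np.full(m, top_c), top + j, top + jn]))  # +Z cap
    return np.vstack(faces)


def generate_fibula_mesh(params: FibulaParams) -> TriMesh:
    """Watertight fibula-analog tube, long axis +Z, vestibular flat facing +X."""
    profile = cross_section_profile(params)
    m = params.circumferential_resolution
    zs = np.linspace(0.0, params.shaft_length, params.axial_resolution)
    rings = []
    for z in zs:
        ring = np.column_stack([
            profile[:, 0],
            profile[:, 1] + _bow(params, z),
            np.full(m, z),
        ])
        rings.append(ring)
    bot_c = [0.0, _bow(params, 0.0), 0.0]
    top_c = [0.0, _bow(params, params.shaft_length), params.shaft_length]
    vertices = np.vstack(rings + [bot_c, top_c])
    faces = _tube_faces(len(zs), m)
    return TriMesh(vertices, faces)


# ---------------------------------------------------------------------------
# Virtual surgical plan
# ---------------------------------------------------------------------------

@dataclass
class SegmentPlan:
    """Planned geometry of one fibula segment.

    Planes carry outward normals (pointing away from the segment
    interior). ``pose`` maps the segment from the fibula frame into the
    planned neomandible frame; poses are produced by exact plane mating
    of the planned cut planes, so the planned assembly closes every
    wedge with zero gap. ``silhouette`` is the mid-slab outer boundary
    polygon (fibula frame) used for length metrology.
    """

    segment_id: int
    proximal_plane: Plane
    distal_plane: Plane
    axis_u: np.ndarray
    vestibular_dir: np.ndarray
    length_vest: float
    length_ling: float
    pose: RigidTransform
    silhouette: np.ndarray
    vest_point: np.ndarray
    ling_point: np.ndarray

    def __post_init__(self) -> None:
        self.axis_u = np.asarray(self.axis_u, dtype=float).reshape(3)
        self.vestibular_dir = np.asarray(self.vestibular_dir, dtype=float).reshape(3)
        self.length_vest = float(self.length_vest)
        self.length_ling = float(self.length_ling)
        if abs(self.axis_u @ self.vestibular_dir) > 1e-9:
            raise ContractError("vestibular_dir must be perpendicular to axis_u")
        if self.length_ling < MIN_LINGUAL_LENGTH_MM - 1e-12:
            raise PlanValidationError(
                f"segment {self.segment_id}: planned lingual length "
                f"{self.length_ling:.2f} mm < {MIN_LINGUAL_LENGTH_MM} mm minimum"
            )


def make_plan(
    params: FibulaParams,
    segment_lengths=(30.0, 32.0, 30.0),
    wedge_angles=(45.0, 45.0),
) -> list[SegmentPlan]:
    """Plan a three-segment reconstruction with closing wedges at the joints.

    ``segment_lengths`` are the planned vestibular (outer-edge) lengths.
    Each inter-segment wedge is realised by symmetric half-angle tilts of
    the two mating planes about the horizontal (Y) axis, with the wedge
    apex on the vestibular edge so the wedge opens lingually — the
    classic closing-wedge osteotomy. Terminal cuts are transverse.
    Raises :class:`PlanValidationError` when any lingual length falls
    below the 20 mm perfusion minimum.
    """
    segment_lengths = [float(v) for v in segment_lengths]
    wedge_angles = [float(v) for v in wedge_angles]
    n_seg = len(segment_lengths)
    if len(wedge_angles) != n_seg - 1:
        raise ContractError("need one wedge angle per joint (n_segments - 1)")
    if params.curvature != 0.0 and any(w != 0.0 for w in wedge_angles):
        # wedge-apex bookkeeping below assumes a straight vestibular edge
        raise ContractError("wedged plans require a straight shaft (curvature 0)")

    profile = cross_section_profile(params)
    x_max = profile[:, 0].max()
    x_min = profile[:, 0].min()
    width = x_max - x_min
    halves = [math.radians(w) / 2.0 for w in wedge_angles]

    total = sum(segment_lengths)
    margin = (params.shaft_length - total) / 2.0
    reach = width * max([math.tan(h) for h in halves], default=0.0)
    if margin <= reach:
        raise PlanValidationError(
            f"shaft_length {params.shaft_length} mm too short for planned total "
            f"{total} mm plus wedge reach {reach:.1f} mm"
        )

    z_top = params.shaft_length - margin
    apex = np.concatenate([[z_top], z_top - np.cumsum(segment_lengths)])

    ez = np.array([0.0, 0.0, 1.0])
    ex = np.array([1.0, 0.0, 0.0])

    def joint_planes(z_apex: float, half: float) -> tuple[Plane, Plane]:
        """(distal plane of upper segment, proximal plane of lower segment)."""
        p = np.array([x_max, 0.0, z_apex])
        s, c = math.sin(half), math.cos(half)
        upper_distal = Plane(p, np.array([-s, 0.0, -c]))
        lower_proximal = Plane(p, np.array([-s, 0.0, c]))
        return upper_distal, lower_proximal

    # walk down the shaft building each segment's two planes
    plans: list[SegmentPlan] = []
    poses: list[RigidTransform] = []
    from .reconstruction import mate_planes  # deterministic plane mating

    for i in range(n_seg):
        h_prox = halves[i - 1] if i > 0 else 0.0
        h_dist = halves[i] if i < n_seg - 1 else 0.0
        if i == 0:
            prox = Plane(np.array([x_max, 0.0, apex[0]]), ez)
        else:
            _, prox = joint_planes(apex[i], halves[i - 1])
        if i == n_seg - 1:
            dist = Plane(np.array([x_max, 0.0, apex[-1]]), -ez)
        else:
            dist, _ = joint_planes(apex[i + 1], halves[i])

        l_vest = segment_lengths[i]
        l_ling = l_vest - width * (math.tan(h_prox) + math.tan(h_dist))

        z_mid = 0.5 * (apex[i] + apex[i + 1])
        silhouette = np.column_stack([
            profile[:, 0],
            profile[:, 1] + _bow(params, z_mid),
            np.full(len(profile), z_mid),
        ])
        jv = int(np.argmax(profile[:, 0]))
        jl = int(np.argmin(profile[:, 0]))

        if i == 0:
            pose = RigidTransform.identity()
        else:
            prev = plans[i - 1]
            pose = mate_planes(
                prox, ex,
                prev.distal_plane.transformed(poses[i - 1]),
                poses[i - 1].rotation @ ex,
            )
        poses.append(pose)
        plans.append(SegmentPlan(
            segment_id=i + 1,
            proximal_plane=prox,
            distal_plane=dist,
            axis_u=ez.copy(),
            vestibular_dir=ex.copy(),
            length_vest=l_vest,
            length_ling=l_ling,
            pose=pose,
            silhouette=silhouette,
            vest_point=silhouette[jv].copy(),
            ling_point=silhouette[jl].copy(),
        ))
    return plans


# ---------------------------------------------------------------------------
# Executed-cut perturbation
# ---------------------------------------------------------------------------

@dataclass
class PerturbationModel:
    """Gaussian shift/tilt model for executed osteotomy planes.

    Each planned plane is translated along the segment axis by
    N(shift_mean, shift_sd) mm plus ``outward_shift_mean`` mm along the
    face's outward axial direction (positive = segment lengthening /
    over-contouring), and its normal is tilted by N(tilt_mean, tilt_sd)
    degrees about a random (or fixed) in-plane azimuth. With
    ``truncate_at_groove_bound`` the tilt magnitude is rejection-sampled
    to stay within the groove restriction of the guide.
    """

    shift_mean: float = 0.0
    shift_sd: float = 0.0
    tilt_mean: float = 0.0
    tilt_sd: float = 0.0
    tilt_azimuth: str | float = "uniform"
    truncate_at_groove_bound: bool = False
    outward_shift_mean: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.shift_sd < 0 or self.tilt_sd < 0:
            raise ContractError("standard deviations must be >= 0")


def _sample_tilt(rng: np.random.Generator, model: PerturbationModel,
                 bound_deg: float) -> float:
    theta = rng.normal(model.tilt_mean, model.tilt_sd)
    if math.isinf(bound_deg):
        return theta
    tries = 0
    while abs(theta) > bound_deg:
        theta = rng.normal(model.tilt_mean, model.tilt_sd)
        tries += 1
        if tries > 100_000:
            raise ContractError(
                "tilt rejection sampling failed: tilt distribution lies almost "
                f"entirely outside the groove bound {bound_deg:.3f} deg"
            )
    return theta


def _perturb_plane(plane: Plane, axis_u: np.ndarray, outward_sign: float,
                   model: PerturbationModel, bound_deg: float,
                   rng: np.random.Generator) -> Plane:
    delta = rng.normal(model.shift_mean, model.shift_sd)
    theta = _sample_tilt(rng, model, bound_deg)
    if model.tilt_azimuth == "uniform":
        phi = rng.uniform(0.0, 2.0 * math.pi)
    else:
        phi = math.radians(float(model.tilt_azimuth))
    point = plane.point + (delta + outward_sign * model.outward_shift_mean) * axis_u
    n = plane.normal
    e1 = axis_u - (axis_u @ n) * n
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([1.0, 0.0, 0.0]) - n[0] * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    axis = math.cos(phi) * e1 + math.sin(phi) * e2
    rot = Rotation.from_rotvec(math.radians(theta) * axis)
    return Plane(point, rot.apply(n))


def perturb_plan(
    plan: list[SegmentPlan],
    model: PerturbationModel,
    guide: GuideGeometry,
    seed=None,
) -> list[tuple[Plane, Plane]]:
    """Executed (proximal, distal) plane pair per segment.

    Every segment plane is perturbed independently — each cut is executed
    through its own guide slot, and the study counts osteotomy planes per
    segment (two per segment, 540 in the default design). Deterministic
    given ``seed`` (an int or :class:`numpy.random.SeedSequence`); draw
    order per plane is shift, tilt (with rejection), azimuth.
    """
    if seed is None:
        seed = model.seed if model.seed is not None else 0
    rng = np.random.default_rng(seed)
    bound = groove_tilt_bound(guide) if model.truncate_at_groove_bound else math.inf
    executed = []
    for sp in plan:
        prox = _perturb_plane(sp.proximal_plane, sp.axis_u, +1.0, model, bound, rng)
        dist = _perturb_plane(sp.distal_plane, sp.axis_u, -1.0, model, bound, rng)
        executed.append((prox, dist))
    return executed


# ---------------------------------------------------------------------------
# Segment meshes (analytic extrude-and-cap, no booleans)
# ---------------------------------------------------------------------------

@dataclass
class SegmentMesh:
    """One executed segment: watertight mesh + ground-truth cut-face labels."""

    segment_id: int
    mesh: TriMesh
    proximal_vertices: np.ndarray
    distal_vertices: np.ndarray

    @property
    def labels(self) -> dict[str, np.ndarray]:
        return {"proximal": self.proximal_vertices, "distal": self.distal_vertices}


def _column_plane_z(params: FibulaParams, px: float, py: float,
                    plane: Plane) -> float:
    """Axial position where the column line (px, py + bow(z), z) meets a plane.

    With a bowed shaft the intersection is a quadratic in z; the root
    closest to the shaft span is taken.
    """
    nx, ny, nz = plane.normal
    rhs = plane.normal @ plane.point
    L = params.shaft_length
    a = -0.5 * ny * params.curvature
    b = nz + 0.5 * ny * params.curvature * L
    c = nx * px + ny * py - rhs
    if abs(a) < 1e-14:
        if abs(b) < 1e-9:
            raise DegenerateGeometryError("cut plane nearly parallel to shaft axis")
        return -c / b
    disc = b * b - 4 * a * c
    if disc < 0:
        raise DegenerateGeometryError("cut plane misses bowed shaft column")
    r1 = (-b + math.sqrt(disc)) / (2 * a)
    r2 = (-b - math.sqrt(disc)) / (2 * a)
    mid = 0.5 * L
    return r1 if abs(r1 - mid) <= abs(r2 - mid) else r2


def build_segments(
    params: FibulaParams,
    executed_planes: list[tuple[Plane, Plane]],
) -> list[SegmentMesh]:
    """Re-extrude the shaft cross-section between executed plane pairs.

    Each segment is built analytically: every cross-section boundary
    column is intersected with the segment's two executed planes, the
    side surface is lofted between the intersections, and the ends are
    capped with planar fans whose vertices lie exactly on the executed
    planes. Cap vertices carry ground-truth proximal/distal labels.
    Raises :class:`DegenerateGeometryError` if the planes give any
    column a non-positive length.
    """
    profile = cross_section_profile(params)
    m = len(profile)
    spacing = params.shaft_length / params.axial_resolution
    out = []
    for idx, (prox, dist) in enumerate(executed_planes):
        z_top = np.array([_column_plane_z(params, px, py, prox) for px, py in profile])
        z_bot = np.array([_column_plane_z(params, px, py, dist) for px, py in profile])
        if np.any(z_top - z_bot <= 0):
            raise DegenerateGeometryError(
                f"segment {idx + 1}: executed planes cross inside the cross-section"
            )
        n_rings = max(2, int(math.ceil((z_top - z_bot).max() / spacing)) + 1)
        f = np.linspace(0.0, 1.0, n_rings)[:, None]          # distal -> proximal
        z = z_bot[None, :] * (1 - f) + z_top[None, :] * f     # (n_rings, m)
        xs = np.broadcast_to(profile[:, 0], z.shape)
        ys = profile[:, 1][None, :] + _bow(params, z)
        vertices = np.column_stack([xs.ravel(), ys.ravel(), z.ravel()])
        zc_bot = _column_plane_z(params, 0.0, 0.0, dist)
        zc_top = _column_plane_z(params, 0.0, 0.0, prox)
        centres = np.array([
            [0.0, _bow(params, zc_bot), zc_bot],
            [0.0, _bow(params, zc_top), zc_top],
        ])
        vertices = np.vstack([vertices, centres])
        faces = _tube_faces(n_rings, m)
        mesh = TriMesh(vertices, faces)
        distal_idx = np.concatenate([np.arange(m), [n_rings * m]])
        prox_idx = np.concatenate([(n_rings - 1) * m + np.arange(m), [n_rings * m + 1]])
        out.append(SegmentMesh(idx + 1, mesh, prox_idx, distal_idx))
    return out


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

def guide_for_cell(design: str, height: float, instrument: str) -> GuideGeometry:
    return GuideGeometry(
        slot_width=SLOT_WIDTH_MM,
        blade_kerf=KERF_MM[instrument],
        guide_height=height,
        design=design,
        instrument=instrument,
    )


def default_perturbation(design: str, height: float, instrument: str) -> PerturbationModel:
    """Study-condition perturbation model for one factorial cell.

    The physical study reports no error distributions, so these are the
    package's fixed emulation conditions: a common Gaussian shift/tilt
    error per cut, a positive lengthening bias for the standard slot
    (over-contouring), a negative bias and unbounded, larger tilt for
    the unilaterally guided flange (under-contouring), and groove-bound
    truncation for the bilaterally walled designs (SS, AS), through
    which the guide-height and instrument-kerf effects act.
    """
    shift_sd = 0.4 if instrument == "saw" else 0.35
    tilt_sd = 2.0 if instrument == "saw" else 1.8
    if design == "SS":
        return PerturbationModel(shift_sd=shift_sd, tilt_sd=tilt_sd,
                                 outward_shift_mean=0.3,
                                 truncate_at_groove_bound=True)
    if design == "AS":
        return PerturbationModel(shift_sd=shift_sd, tilt_sd=tilt_sd,
                                 truncate_at_groove_bound=True)
    return PerturbationModel(shift_sd=shift_sd, tilt_sd=3.0,
                             outward_shift_mean=-0.2,
                             truncate_at_groove_bound=False)


@dataclass
class StudyDesign:
    """The factorial design: designs x heights x instruments x replicates."""

    designs: tuple = _DESIGNS
    heights: tuple = (1.0, 2.0, 3.0)
    instruments: tuple = _INSTRUMENTS
    replicates: int = 5
    segments_per_fibula: int = 3
    segment_lengths: tuple = (30.0, 32.0, 30.0)
    wedge_angles: tuple = (45.0, 45.0)
    fibula: FibulaParams = field(default_factory=FibulaParams)
    perturbation_overrides: dict = field(default_factory=dict)
    slot_width: float = SLOT_WIDTH_MM
    kerf: dict = field(default_factory=lambda: dict(KERF_MM))

    def __post_init__(self) -> None:
        if len(self.segment_lengths) != self.segments_per_fibula:
            raise ContractError("segment_lengths must match segments_per_fibula")
        for d in self.designs:
            if d not in _DESIGNS:
                raise ContractError(f"unknown design {d!r}")
        for ins in self.instruments:
            if ins not in _INSTRUMENTS:
                raise ContractError(f"unknown instrument {ins!r}")
        # fail fast on impossible groove geometry (kerf >= slot width)
        for _, d, h, ins in self.cells():
            self.guide_for(d, h, ins)

    def guide_for(self, design: str, height: float, instrument: str) -> GuideGeometry:
        return GuideGeometry(
            slot_width=self.slot_width,
            blade_kerf=self.kerf[instrument],
            guide_height=height,
            design=design,
            instrument=instrument,
        )

    def cells(self):
        """Yield (cell_index, design, height, instrument)."""
        idx = 0
        for d in self.designs:
            for h in self.heights:
                for ins in self.instruments:
                    yield idx, d, float(h), ins
                    idx += 1

    @property
    def n_fibulae(self) -> int:
        return len(self.designs) * len(self.heights) * len(self.instruments) * self.replicates

    def perturbation_for(self, design: str, height: float, instrument: str) -> PerturbationModel:
        key = (design, float(height), instrument)
        if key in self.perturbation_overrides:
            return self.perturbation_overrides[key]
        return default_perturbation(design, height, instrument)

    @staticmethod
    def fibula_seed(master_seed: int, cell_index: int, replicate: int) -> np.random.SeedSequence:
        """Counter scheme: one independent stream per (cell, replicate)."""
        return np.random.SeedSequence(entropy=(int(master_seed), int(cell_index), int(replicate)))
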