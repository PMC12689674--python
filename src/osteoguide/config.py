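"""Run configuration: one YAML file reproduces the whole virtual study.

The config file is a nested YAML mapping with sections ``design``,
``fibula``, ``guide``, ``perturbation``, ``icp`` and ``pipeline``; every
key is optional (a file containing only ``seed: 1`` is valid) and
unknown keys are rejected by name. CLI flags override config values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mesh_core import ContractError, OsteoguideError, Plane, RigidTransform
from .synthetic_fibula import (
    KERF_MM,
    SLOT_WIDTH_MM,
    FibulaParams,
    PerturbationModel,
    SegmentPlan,
    StudyDesign,
)

__all__ = ["RunConfig", "ConfigError", "validate_config", "plan_to_dict", "plan_from_dict"]


class ConfigError(OsteoguideError):
    """The run configuration is invalid."""


@dataclass
class RunConfig:
    """Fully-defaulted, validated configuration of a study run."""

    seed: int = 0
    output_dir: str = "osteoguide_out"
    design: StudyDesign = field(default_factory=StudyDesign)
    icp_subsample: int = 2000
    icp_max_iterations: int = 100
    icp_tol: float = 1e-6
    with_reconstruction: bool = True
    detect_faces: bool = False
    export_heatmaps: bool = False


def _take(section: dict, allowed: dict, where: str) -> dict:
    """Pop known keys (with casting) from a config section; reject the rest."""
    out = {}
    for key, cast in allowed.items():
        if key in section:
            try:
                out[key] = cast(section.pop(key))
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{where}.{key}: {exc}") from exc
    if section:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(section)}")
    return out


def _float_tuple(v):
    return tuple(float(x) for x in v)


def _str_tuple(v):
    return tuple(str(x) for x in v)


def validate_config(path) -> RunConfig:
    """Load, default and validate a YAML run configuration.

    Raises :class:`ConfigError` for unknown keys, invalid enum values or
    impossible guide geometry (kerf >= slot width).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    top = _take(dict(raw), {
        "seed": int, "output_dir": str, "design": dict, "fibula": dict,
        "guide": dict, "perturbation": list, "icp": dict, "pipeline": dict,
    }, "config")

    fib_kwargs = _take(top.get("fibula", {}), {
        "shaft_length": float, "cross_section_width": float,
        "cross_section_shape": float, "curvature": float,
        "axial_resolution": int, "circumferential_resolution": int, "seed": int,
    }, "fibula")

    guide_kwargs = _take(top.get("guide", {}), {
        "slot_width": float, "kerf_saw": float, "kerf_piezo": float,
    }, "guide")
    kerf = dict(KERF_MM)
    if "kerf_saw" in guide_kwargs:
        kerf["saw"] = guide_kwargs["kerf_saw"]
    if "kerf_piezo" in guide_kwargs:
        kerf["piezo"] = guide_kwargs["kerf_piezo"]

    design_kwargs = _take(top.get("design", {}), {
        "designs": _str_tuple, "heights": _float_tuple,
        "instruments": _str_tuple, "replicates": int,
        "segments_per_fibula": int, "segment_lengths": _float_tuple,
        "wedge_angles": _float_tuple,
    }, "design")

    overrides = {}
    for i, entry in enumerate(top.get("perturbation", [])):
        entry = dict(entry)
        where = f"perturbation[{i}]"
        cell = _take({k: entry.pop(k) for k in ("design", "height", "instrument")
                      if k in entry},
                     {"design": str, "height": float, "instrument": str}, where)
        if set(cell) != {"design", "height", "instrument"}:
            raise ConfigError(f"{where}: needs design, height and instrument keys")
        model_kwargs = _take(entry, {
            "shift_mean": float, "shift_sd": float, "tilt_mean": float,
            "tilt_sd": float, "tilt_azimuth": lambda v: v,
            "truncate_at_groove_bound": bool, "outward_shift_mean": float,
        }, where)
        try:
            overrides[(cell["design"], cell["height"], cell["instrument"])] = \
                PerturbationModel(**model_kwargs)
        except ContractError as exc:
            raise ConfigError(f"{where}: {exc}") from exc

    icp_kwargs = _take(top.get("icp", {}), {
        "subsample": int, "max_iterations": int, "tol": float,
    }, "icp")
    pipe_kwargs = _take(top.get("pipeline", {}), {
        "with_reconstruction": bool, "detect_faces": bool, "export_heatmaps": bool,
    }, "pipeline")

    try:
        design = StudyDesign(
            fibula=FibulaParams(**fib_kwargs),
            perturbation_overrides=overrides,
            slot_width=guide_kwargs.get("slot_width", SLOT_WIDTH_MM),
            kerf=kerf,
            **design_kwargs,
        )
    except ContractError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        seed=top.get("seed", 0),
        output_dir=top.get("output_dir", "osteoguide_out"),
        design=design,
        icp_subsample=icp_kwargs.get("subsample", 2000),
        icp_max_iterations=icp_kwargs.get("max_iterations", 100),
        icp_tol=icp_kwargs.get("tol", 1e-6),
        with_reconstruction=pipe_kwargs.get("with_reconstruction", True),
        detect_faces=pipe_kwargs.get("detect_faces", False),
        export_heatmaps=pipe_kwargs.get("export_heatmaps", False),
    )


# ---------------------------------------------------------------------------
# Plan serialisation (human-readable sidecar for the disk pipeline)
# ---------------------------------------------------------------------------

def plan_to_dict(plan: list[SegmentPlan]) -> dict:
    return {"segments": [
        {
            "segment_id": sp.segment_id,
            "proximal_plane": {"point": sp.proximal_plane.point.tolist(),
                               "normal": sp.proximal_plane.normal.tolist()},
            "distal_plane": {"point": sp.distal_plane.point.tolist(),
                             "normal": sp.distal_plane.normal.tolist()},
            "axis_u": sp.axis_u.tolist(),
            "vestibular_dir": sp.vestibular_dir.tolist(),
            "length_vest": sp.length_vest,
            "length_ling": sp.length_ling,
            "pose": sp.pose.as_matrix().tolist(),
            "silhouette": sp.silhouette.tolist(),
            "vest_point": sp.vest_point.tolist(),
            "ling_point": sp.ling_point.tolist(),
        }
        for sp in plan
    ]}


def plan_from_dict(data: dict) -> list[SegmentPlan]:
    plan = []
    for s in data["segments"]:
        pose = np.asarray(s["pose"], dtype=float)
        plan.append(SegmentPlan(
            segment_id=int(s["segment_id"]),
            proximal_plane=Plane(s["proximal_plane"]["point"], s["proximal_plane"]["normal"]),
            distal_plane=Plane(s["distal_plane"]["point"], s["distal_plane"]["normal"]),
            axis_u=np.asarray(s["axis_u"], dtype=float),
            vestibular_dir=np.asarray(s["vestibular_dir"], dtype=float),
            length_vest=float(s["length_vest"]),
            length_ling=float(s["length_ling"]),
            pose=RigidTransform(pose[:3, :3], pose[:3, 3]),
            silhouette=np.asarray(s["silhouette"], dtype=float),
            vest_point=np.asarray(s["vest_point"], dtype=float),
            ling_point=np.asarray(s["ling_point"], dtype=float),
        ))
    return plan
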