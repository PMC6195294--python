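"""Assembly and export of a 17-segment whole-dog rigid-body model.

A :class:`DogModel` is a parameter file, not a kinematic chain: per
segment it records mass, length, CoM position along the proximal-distal
axis and the inertia tensor about the CoM in the segment frame.  The
frame convention follows the measurement protocol: yy is the
flexion/extension axis, oriented right-to-left for every segment except
the crus; the right brachium was measured with its axes reversed, which
a y-axis reflection encodes by negating the products P_xy and P_yz
(diagonal moments are invariant under reflection).

Models round-trip losslessly through JSON or YAML with an embedded
schema version and per-field units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .bsp_reference import (
    AXIAL_SEGMENTS,
    LIMB_SEGMENTS,
    SegmentId,
    all_segments,
    reference_dog,
    scale_to_dog,
)
from .inertial_math import InertiaTensor

__all__ = [
    "SegmentModel",
    "DogModel",
    "AssemblyError",
    "MassClosureWarning",
    "SCHEMA_VERSION",
    "build",
    "build_from_reference",
    "reverse_y_axis",
    "export_model",
    "import_model",
    "whole_body_com",
]

SCHEMA_VERSION = "1.0"


class AssemblyError(ValueError):
    """Model assembly failed (missing segments, bad counts)."""


class MassClosureWarning(UserWarning):
    """Sum of segment masses strays from the whole-body mass."""


@dataclass(frozen=True)
class SegmentModel:
    """Inertial parameters of one concrete segment in its own frame."""

    id: SegmentId
    mass: float
    length: float
    com_from_proximal: float
    tensor: InertiaTensor
    frame: str = "yy=flexion/extension, right-to-left (crus reversed)"

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"{self.id}: mass must be > 0")
        if not 0.0 <= self.com_from_proximal <= self.length:
            raise ValueError(
                f"{self.id}: CoM {self.com_from_proximal} outside [0, {self.length}]"
            )


@dataclass
class DogModel:
    """Whole-dog parameter set: exactly 17 segments plus provenance."""

    dog_id: str
    body_mass: float
    segments: dict[str, SegmentModel]
    provenance: dict[str, str] = field(default_factory=dict)
    mass_closure_ratio: float = float("nan")

    def __post_init__(self):
        expected = {str(s) for s in all_segments()}
        got = set(self.segments)
        if got != expected:
            raise AssemblyError(
                f"model needs the 17 standard segments; missing {sorted(expected - got)}, "
                f"unexpected {sorted(got - expected)}"
            )

    def segment(self, name: str, side: str = "none") -> SegmentModel:
        key = name if side == "none" else f"{side}_{name}"
        return self.segments[key]

    def total_segment_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())


def reverse_y_axis(tensor: InertiaTensor) -> InertiaTensor:
    """Re-express a tensor after reversing the y axis (a reflection).

    Under y -> -y the integrals ∫xy dm and ∫yz dm change sign while the
    diagonal moments and ∫xz dm are invariant.
    """
    return InertiaTensor(
        i_xx=tensor.i_xx, i_yy=tensor.i_yy, i_zz=tensor.i_zz,
        p_xy=-tensor.p_xy, p_xz=tensor.p_xz, p_yz=-tensor.p_yz,
        frame_point=tensor.frame_point,
        axes_label=tensor.axes_label + " (y reversed)",
    )


def build(
    bsps: Mapping[str, tuple[float, float, float, InertiaTensor]],
    body_mass: float,
    dog_id: str = "synthetic",
    provenance: str = "user",
    mass_tolerance: float = 0.02,
    reverse_right_brachium: bool = True,
) -> DogModel:
    """Assemble a :class:`DogModel` from per-segment-name parameters.

    ``bsps`` maps each of the 11 anatomical names to
    ``(mass, length, com_from_proximal, tensor_about_com)``; limb entries
    are mirrored to both sides (pooled left/right data).  The right
    brachium's frame is y-reversed per the measurement convention.  A
    segment-mass sum off the body mass by more than ``mass_tolerance``
    (fractional) triggers a :class:`MassClosureWarning`.
    """
    missing = [n for n in AXIAL_SEGMENTS + LIMB_SEGMENTS if n not in bsps]
    if missing:
        raise AssemblyError(f"missing segments: {missing}")
    segments: dict[str, SegmentModel] = {}
    for name in AXIAL_SEGMENTS:
        mass, length, com, tensor = bsps[name]
        segments[name] = SegmentModel(SegmentId(name), mass, length, com, tensor)
    for name in LIMB_SEGMENTS:
        mass, length, com, tensor = bsps[name]
        for side in ("left", "right"):
            t = tensor
            if name == "brachium" and side == "right" and reverse_right_brachium:
                t = reverse_y_axis(tensor)
            segments[f"{side}_{name}"] = SegmentModel(
                SegmentId(name, side), mass, length, com, t
            )
    total = sum(s.mass for s in segments.values())
    ratio = total / body_mass
    if abs(ratio - 1.0) > mass_tolerance:
        warnings.warn(
            f"segment masses sum to {ratio:.4f} of body mass "
            f"(tolerance {mass_tolerance:.1%})",
            MassClosureWarning, stacklevel=2,
        )
    return DogModel(
        dog_id=dog_id,
        body_mass=body_mass,
        segments=segments,
        provenance={k: provenance for k in segments},
        mass_closure_ratio=ratio,
    )


def build_from_reference(
    body_mass: float | None = None,
    segment_lengths: Mapping[str, float] | None = None,
    dog_id: str = "reference",
    mass_tolerance: float = 0.02,
) -> DogModel:
    """Build a model from the packaged reference tables.

    Defaults to the cohort-mean body mass and the derived reference
    segment lengths; pass ``segment_lengths`` (name -> m) to scale to a
    measured dog.
    """
    if body_mass is None:
        body_mass = reference_dog().body_mass
    bsps = {}
    for name in AXIAL_SEGMENTS + LIMB_SEGMENTS:
        from .bsp_reference import lookup  # local import avoids cycle at module load

        ref, _ = lookup(name)
        length = (segment_lengths or {}).get(name, ref.l_ref)
        scaled = scale_to_dog(name, body_mass, length)
        bsps[name] = (scaled.mass, length, scaled.com_from_proximal, scaled.tensor)
    return build(
        bsps, body_mass, dog_id=dog_id, provenance="reference tables",
        mass_tolerance=mass_tolerance,
    )


def _tensor_to_dict(t: InertiaTensor) -> dict:
    return {
        "i_xx": t.i_xx, "i_yy": t.i_yy, "i_zz": t.i_zz,
        "p_xy": t.p_xy, "p_xz": t.p_xz, "p_yz": t.p_yz,
        "frame_point": t.frame_point, "axes_label": t.axes_label,
        "units": "kg.m^2",
    }


def _tensor_from_dict(d: dict) -> InertiaTensor:
    return InertiaTensor(
        i_xx=d["i_xx"], i_yy=d["i_yy"], i_zz=d["i_zz"],
        p_xy=d["p_xy"], p_xz=d["p_xz"], p_yz=d["p_yz"],
        frame_point=d["frame_point"], axes_label=d["axes_label"],
    )


def export_model(model: DogModel, fmt: str = "yaml") -> str:
    """Serialize a model to a JSON or YAML document (lossless round trip)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "dog_id": model.dog_id,
        "body_mass_kg": model.body_mass,
        "mass_closure_ratio": model.mass_closure_ratio,
        "frame_origin": "proximal endpoint; tensors about the CoM "
                        "(shift with the parallel-axis transform)",
        "segments": {
            key: {
                "name": s.id.name,
                "side": s.id.side,
                "mass_kg": s.mass,
                "length_m": s.length,
                "com_from_proximal_m": s.com_from_proximal,
                "frame": s.frame,
                "tensor": _tensor_to_dict(s.tensor),
                "provenance": model.provenance.get(key, ""),
            }
            for key, s in sorted(model.segments.items())
        },
    }
    if fmt == "json":
        return json.dumps(doc, indent=2, sort_keys=True)
    if fmt == "yaml":
        return yaml.safe_dump(doc, sort_keys=True)
    raise ValueError(f"unknown format {fmt!r}")


def import_model(document: str, fmt: str | None = None) -> DogModel:
    """Parse an exported model document; validates the 17-segment shape."""
    if fmt == "json" or (fmt is None and document.lstrip().startswith("{")):
        doc = json.loads(document)
    else:
        doc = yaml.safe_load(document)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise AssemblyError(
            f"unsupported schema version {doc.get('schema_version')!r}"
        )
    segments = {}
    provenance = {}
    for key, s in doc["segments"].items():
        segments[key] = SegmentModel(
            id=SegmentId(s["name"], s["side"]),
            mass=s["mass_kg"],
            length=s["length_m"],
            com_from_proximal=s["com_from_proximal_m"],
            tensor=_tensor_from_dict(s["tensor"]),
            frame=s["frame"],
        )
        provenance[key] = s.get("provenance", "")
    return DogModel(
        dog_id=doc["dog_id"],
        body_mass=doc["body_mass_kg"],
        segments=segments,
        provenance=provenance,
        mass_closure_ratio=doc.get("mass_closure_ratio", float("nan")),
    )


def whole_body_com(
    model: DogModel, placements: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """Mass-weighted whole-body CoM for a given posture.

    ``placements`` maps each segment key to ``(proximal_point, axis_unit)``
    in a common world frame; each segment's CoM sits at
    ``proximal + com_from_proximal * axis``.  The result depends only on
    masses and CoM positions, so it is invariant under the left/right
    frame-convention choice (which touches only tensor products).
    """
    total = model.total_segment_mass()
    acc = np.zeros(3)
    for key, seg in model.segments.items():
        origin, axis = placements[key]
        origin = np.asarray(origin, dtype=float)
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        acc += seg.mass * (origin + seg.com_from_proximal * axis)
    return acc / total
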