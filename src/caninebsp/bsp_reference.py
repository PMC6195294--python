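"""Packaged German Shepherd body-segment-parameter reference set.

The reference cohort is six adult male police-service German Shepherds
(mean body mass 36.8 kg, range 34.29-39.41 kg), divided post mortem into
17 segments: five axial (head, neck, thorax, abdomen, tail) and six limb
segments on each side (brachium, antebrachium, manus, thigh, crus, pes).
Left and right limb measurements are pooled, so both sides of a limb
segment share one reference row.

Shipped data files (``data/segment_reference.yaml`` and
``data/segment_moi.yaml``) hold normalised masses, CoM ratios, densities,
volumes and the full 6-component inertia description per segment, with
cohort SDs.  Accessors return SI units; the MoI file stores values in
1e-4 kg·m² with an explicit ``scale`` field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .inertial_math import InertiaTensor

__all__ = [
    "SegmentId",
    "SegmentReference",
    "SegmentMoIReference",
    "ReferenceDog",
    "ScaledSegment",
    "AXIAL_SEGMENTS",
    "LIMB_SEGMENTS",
    "SEGMENT_NAMES",
    "all_segments",
    "lookup",
    "mass_closure",
    "scale_to_dog",
    "reference_dog",
    "reference_tensor",
    "triangle_report",
    "cut_waste_percent",
    "equivalent_cylinder_length",
    "ExtrapolationWarning",
]

AXIAL_SEGMENTS = ("head", "neck", "thorax", "abdomen", "tail")
LIMB_SEGMENTS = ("brachium", "antebrachium", "manus", "thigh", "crus", "pes")
SEGMENT_NAMES = AXIAL_SEGMENTS + LIMB_SEGMENTS

#: anatomical-axis column names in the MoI table
_ANATOMICAL = ("int_ext", "abd_add", "flx_ext")


class ExtrapolationWarning(UserWarning):
    """Requested dog lies outside the reference cohort's body-mass range."""


@dataclass(frozen=True)
class SegmentId:
    """One of the 17 concrete segments: an anatomical name plus a side."""

    name: str
    side: str = "none"

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise KeyError(f"unknown segment name {self.name!r}")
        if self.side not in ("left", "right", "none"):
            raise ValueError(f"unknown side {self.side!r}")
        axial = self.name in AXIAL_SEGMENTS
        if axial and self.side != "none":
            raise ValueError(f"axial segment {self.name} takes side='none'")
        if not axial and self.side == "none":
            raise ValueError(f"limb segment {self.name} needs side left/right")

    def __str__(self):
        return self.name if self.side == "none" else f"{self.side}_{self.name}"


def all_segments() -> tuple[SegmentId, ...]:
    """The 17 concrete segments of the whole-dog model."""
    out = [SegmentId(n) for n in AXIAL_SEGMENTS]
    for n in LIMB_SEGMENTS:
        out.append(SegmentId(n, "left"))
        out.append(SegmentId(n, "right"))
    return tuple(out)


@dataclass(frozen=True)
class SegmentReference:
    """Normalised mass, CoM ratios, density and volume with cohort SDs."""

    name: str
    endpoints: str
    mass_fraction: float
    mass_fraction_sd: float
    com_ratio_prox: float
    com_ratio_prox_sd: float
    com_ratio_dist: float
    com_ratio_dist_sd: float
    density: float          # kg/m3
    density_sd: float
    volume_m3: float
    volume_sd_m3: float
    l_ref: float            # m, derived equivalent-cylinder length


@dataclass(frozen=True)
class SegmentMoIReference:
    """Per-segment moments/products of inertia (SI kg·m²) and axis mapping.

    ``axis_map`` sends each box axis (xx, yy, zz) to the anatomical
    rotation axis it represents for that segment; yy is always
    flexion/extension.  ``moments`` and ``products`` carry SI values;
    diagonal moments are positive, products keep their measured signs
    (the tail row includes large negative products and violates the
    perpendicular-axis inequality -- a documented property of the data).
    """

    name: str
    moments: Mapping[str, float]      # keys int_ext, abd_add, flx_ext
    moments_sd: Mapping[str, float]
    products: Mapping[str, float]     # keys p_xy, p_xz, p_yz
    products_sd: Mapping[str, float]
    axis_map: Mapping[str, str]

    def moment_for_box_axis(self, axis: str) -> float:
        return self.moments[self.axis_map[axis]]


@dataclass(frozen=True)
class ReferenceDog:
    """Cohort-level metadata of the reference data set."""

    body_mass: float
    body_mass_range: tuple[float, float]
    n: int
    sex: str
    occupation: str
    cut_waste_kg: float


@dataclass(frozen=True)
class ScaledSegment:
    """Output of :func:`scale_to_dog`; CoM offsets off the long axis are
    not available in the reference data, so the CoM sits on the
    proximal-distal axis (``com_on_axis_only`` records the approximation)."""

    segment: SegmentId
    mass: float
    com_from_proximal: float
    tensor: InertiaTensor
    com_on_axis_only: bool = True


def _read_yaml(name: str) -> dict:
    with resources.files("caninebsp.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=1)
def _reference_raw() -> dict:
    return _read_yaml("segment_reference.yaml")


@lru_cache(maxsize=1)
def _moi_raw() -> dict:
    return _read_yaml("segment_moi.yaml")


def equivalent_cylinder_length(mass: float, volume: float, i_flx_ext: float) -> float:
    """Length of the uniform cylinder matching mass, volume and transverse MoI.

    For a cylinder of mass m, volume V = πr²L, the flexion/extension
    (transverse, through-CoM) moment is m(3r² + L²)/12 = m(3V/(πL) + L²)/12.
    Eliminating r leaves the cubic ``m L³ − 12 I L + 3 m V/π = 0``; the
    larger positive root is the elongated solution appropriate for body
    segments measured about a transverse axis.
    """
    if min(mass, volume, i_flx_ext) <= 0:
        raise ValueError("mass, volume and i_flx_ext must be > 0")
    roots = np.roots([mass, 0.0, -12.0 * i_flx_ext, 3.0 * mass * volume / np.pi])
    real = roots[np.abs(roots.imag) < 1e-9 * np.abs(roots).max()].real
    positive = real[real > 0]
    if positive.size == 0:
        raise ValueError("no physical cylinder matches these mass/volume/MoI values")
    return float(positive.max())


@lru_cache(maxsize=None)
def _segment_reference(name: str) -> SegmentReference:
    raw = _reference_raw()
    row = raw["segments"][name]
    mass = row["mass_fraction"] * raw["study"]["body_mass_mean_kg"]
    volume = row["volume_cm3"] * 1e-6
    l_ref = row.get("l_ref_m")
    if l_ref is None:
        moi = _moi_raw()
        i_flx = moi["segments"][name]["i_flx_ext"] * moi["scale"]
        l_ref = equivalent_cylinder_length(mass, volume, i_flx)
    return SegmentReference(
        name=name,
        endpoints=row["endpoints"],
        mass_fraction=row["mass_fraction"],
        mass_fraction_sd=row["mass_fraction_sd"],
        com_ratio_prox=row["com_ratio_prox"],
        com_ratio_prox_sd=row["com_ratio_prox_sd"],
        com_ratio_dist=row["com_ratio_dist"],
        com_ratio_dist_sd=row["com_ratio_dist_sd"],
        density=row["density_kg_m3"],
        density_sd=row["density_sd"],
        volume_m3=volume,
        volume_sd_m3=row["volume_sd"] * 1e-6,
        l_ref=float(l_ref),
    )


@lru_cache(maxsize=None)
def _segment_moi(name: str) -> SegmentMoIReference:
    raw = _moi_raw()
    scale = raw["scale"]
    row = raw["segments"][name]
    moments = {k: row[f"i_{k}"] * scale for k in _ANATOMICAL}
    moments_sd = {k: row[f"i_{k}_sd"] * scale for k in _ANATOMICAL}
    products = {k: row[k] * scale for k in ("p_xy", "p_xz", "p_yz")}
    products_sd = {k: row[f"{k}_sd"] * scale for k in ("p_xy", "p_xz", "p_yz")}
    return SegmentMoIReference(
        name=name,
        moments=moments,
        moments_sd=moments_sd,
        products=products,
        products_sd=products_sd,
        axis_map=dict(row["axis_map"]),
    )


def lookup(segment: SegmentId | str) -> tuple[SegmentReference, SegmentMoIReference]:
    """Reference parameters for a segment; left and right share pooled values."""
    name = segment.name if isinstance(segment, SegmentId) else segment
    if name not in SEGMENT_NAMES:
        raise KeyError(f"unknown segment {name!r}")
    return _segment_reference(name), _segment_moi(name)


def reference_dog() -> ReferenceDog:
    s = _reference_raw()["study"]
    return ReferenceDog(
        body_mass=s["body_mass_mean_kg"],
        body_mass_range=tuple(s["body_mass_range_kg"]),
        n=s["n_dogs"],
        sex=s["sex"],
        occupation=s["occupation"],
        cut_waste_kg=s["cut_waste_kg_per_dog"],
    )


def mass_closure() -> float:
    """Sum of normalised segment masses, limb segments counted twice.

    A whole-dog audit of the mass-fraction table; a complete, consistent
    table sums to 1 within the dissection cut-waste allowance.
    """
    total = sum(_segment_reference(n).mass_fraction for n in AXIAL_SEGMENTS)
    total += 2.0 * sum(_segment_reference(n).mass_fraction for n in LIMB_SEGMENTS)
    return total


def cut_waste_percent() -> float:
    """Dissection tissue loss as a percentage of cohort-mean body mass."""
    dog = reference_dog()
    return 100.0 * dog.cut_waste_kg / dog.body_mass


def reference_tensor(name: str) -> InertiaTensor:
    """SI inertia tensor of a segment in its box axes at the segment CoM."""
    moi = _segment_moi(name)
    return InertiaTensor(
        i_xx=moi.moment_for_box_axis("xx"),
        i_yy=moi.moment_for_box_axis("yy"),
        i_zz=moi.moment_for_box_axis("zz"),
        p_xy=moi.products["p_xy"],
        p_xz=moi.products["p_xz"],
        p_yz=moi.products["p_yz"],
        frame_point="com",
        axes_label=f"{name} box axes",
    )


def triangle_report() -> dict[str, list[str]]:
    """Perpendicular-axis-inequality audit of every packaged tensor.

    Returns ``{segment: [violated permutations...]}`` including empty
    lists, and never raises: the tail row is expected to violate the
    inequality (a property of the measured data, preserved as shipped).
    """
    return {n: reference_tensor(n).triangle_violations() for n in SEGMENT_NAMES}


def scale_to_dog(
    segment: SegmentId | str, body_mass: float, segment_length: float
) -> ScaledSegment:
    """Scale the reference parameters to a target dog.

    mass scales linearly with body mass; the CoM rides at the reference
    proximal ratio of the given segment length; tensor components scale
    by (body_mass / 36.8) · (segment_length / l_ref)², the standard
    mass-and-length-squared normalisation for transferring MoI between
    animals.  Body masses outside the reference cohort range trigger an
    :class:`ExtrapolationWarning`.
    """
    if body_mass <= 0 or segment_length <= 0:
        raise ValueError("body_mass and segment_length must be > 0")
    sid = segment if isinstance(segment, SegmentId) else SegmentId(
        segment, "none" if segment in AXIAL_SEGMENTS else "left"
    )
    ref, _ = lookup(sid)
    dog = reference_dog()
    lo, hi = dog.body_mass_range
    if not lo <= body_mass <= hi:
        warnings.warn(
            f"body mass {body_mass} kg outside reference range [{lo}, {hi}] kg; "
            "scaled parameters are extrapolated",
            ExtrapolationWarning, stacklevel=2,
        )
    k = (body_mass / dog.body_mass) * (segment_length / ref.l_ref) ** 2
    t = reference_tensor(sid.name)
    scaled = InertiaTensor(
        i_xx=t.i_xx * k, i_yy=t.i_yy * k, i_zz=t.i_zz * k,
        p_xy=t.p_xy * k, p_xz=t.p_xz * k, p_yz=t.p_yz * k,
        frame_point="com", axes_label=t.axes_label,
    )
    return ScaledSegment(
        segment=sid,
        mass=ref.mass_fraction * body_mass,
        com_from_proximal=ref.com_ratio_prox * segment_length,
        tensor=scaled,
    )
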