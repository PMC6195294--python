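"""Synthetic dogs, cohorts and pendulum sessions with known ground truth.

Real per-dog raw data for the reference cohort are not published, so
every pipeline input is emulated here: a virtual dog is an assembly of
homogeneous geometric solids whose masses, densities and lengths scatter
around the packaged reference values; the morphometric record is derived
from the generating solids (circumference = 2πr of the solid, length of
the solid, etc.), so geometry-based regression has an exact ground
truth; pendulum sessions forward-simulate small-angle compound-pendulum
oscillation traces (T = 2π√(I_pivot/(m g l))) for the composite and
empty box about all six box axes.

Randomness: every generator is a pure function of ``(spec, seed)``.  A
single seed fans out to independent substreams through
``numpy.random.SeedSequence`` with entropy ``(seed, stream_index)``,
where the stream index is the segment's position in the fixed 17-segment
order (body-level draws use stream 1000+); adding a segment therefore
never perturbs another segment's draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import pendulum as pend
from .bsp_reference import (
    AXIAL_SEGMENTS,
    LIMB_SEGMENTS,
    SEGMENT_NAMES,
    all_segments,
    lookup,
    reference_dog,
)
from .inertial_math import (
    GeometricSolid,
    InertiaTensor,
    cuboid_inertia,
    moi_about_axis,
    solid_inertia,
)
from .pendulum import (
    AXES,
    SKEW_PAIRS,
    BoxCalibration,
    OscillationTrace,
    PendulumTrial,
    estimate_period,
    extract_segment_tensor,
    skew_axis_vector,
)
from .regression import MorphometricRecord, RegressionEquation, build_term

__all__ = [
    "CohortSpec",
    "BoxSpec",
    "SyntheticSegment",
    "SyntheticDog",
    "SegmentSession",
    "PendulumSession",
    "SEGMENT_SHAPES",
    "generate_dog",
    "generate_pendulum_session",
    "invert_session",
    "generate_cohort",
    "generate_cohort_from_equation",
    "nominal_dimensions",
]

#: geometric solid family assigned to each segment, following the shapes
#: the published equations imply (volume-like mass terms: cylinder for
#: slender limbs, frustum for tapering trunk/neck segments, box/pyramid
#: for the pes, ellipsoid for the head, cone for the tail)
SEGMENT_SHAPES: Mapping[str, str] = {
    "manus": "cylinder",
    "antebrachium": "cylinder",
    "brachium": "conical_frustum",
    "pes": "rectangular_pyramid",
    "crus": "cylinder",
    "thigh": "conical_frustum",
    "head": "ellipsoid",
    "neck": "conical_frustum",
    "thorax": "conical_frustum",
    "abdomen": "conical_frustum",
    "tail": "cone",
}

#: distal/proximal radius ratio for frustum segments (proximal end first
#: in the anatomical endpoint order); >1 widens distally
_TAPER: Mapping[str, float] = {
    "brachium": 0.80,   # narrows toward the elbow
    "thigh": 0.75,      # narrows toward the stifle
    "neck": 1.30,       # widens from head to shoulders
    "thorax": 1.25,     # widens from C7/T1 to the last rib
    "abdomen": 0.85,    # narrows toward the waist
}

_PES_ASPECT = 0.8       # base_b / base_a of the pes pyramid
_HEAD_ASPECT = 0.85     # semi_b / semi_a of the head ellipsoid

#: fixed stream indices for body-level draws
_BODY_STREAM = 1000

_SEGMENT_KEYS = tuple(str(s) for s in all_segments())


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, stream)))


def _segment_stream(key: str) -> int:
    return _SEGMENT_KEYS.index(key)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for synthetic cohorts.

    Defaults mirror the reference cohort: 6 dogs pooled over sides gives
    n = 12 limb observations; body mass uniform over the cohort range;
    lognormal dimension scatter at 5 % CV (dispersions for derived BSPs
    come from the packaged SD columns); 1 % relative measurement noise on
    observed BSPs.
    """

    n: int = 12
    seed: int = 0
    body_mass_range: tuple[float, float] = (34.29, 39.41)
    dimension_cv: float = 0.05
    measurement_noise: float = 0.01
    bsp_cv_scale: float = 1.0   # multiplies the table-derived fraction/density CVs

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if min(self.dimension_cv, self.measurement_noise, self.bsp_cv_scale) < 0:
            raise ValueError("dispersions must be >= 0")


@dataclass(frozen=True)
class BoxSpec:
    """Segment-holder and pendulum-rig parameters for forward simulation."""

    foam_density: float = 30.0    # kg/m3, solid-Styrofoam holder
    padding: float = 1.2          # box edge / solid bounding extent
    pendulum_length: float | None = None  # m pivot-to-CoM; None = adaptive
    hang_factor: float = 0.7      # adaptive length = factor x largest box edge
    min_pendulum_length: float = 0.15
    sample_rate: float = 100.0    # Hz
    n_cycles: int = 20
    trials_per_axis: int = 3      # successive swings averaged per axis
    amplitude: float = 1.0        # trace units (small-angle swing, <= 10 deg)
    theta: float = np.pi / 4.0    # skew-axis angle from the pair's second axis
    g: float = 9.81
    misalignment_deg: float = 10.0  # max random tilt of the segment in its box


@dataclass(frozen=True)
class SyntheticSegment:
    """One generated segment: the solid plus its derived ground truth."""

    key: str                      # e.g. "left_manus" or "thorax"
    name: str
    solid: GeometricSolid
    mass: float
    com: np.ndarray               # m, from the proximal end along z
    tensor: InertiaTensor         # about the CoM, solid symmetry frame
    dimensions: dict[str, float]  # morphometric keys "<name>.<letter>"


@dataclass(frozen=True)
class SyntheticDog:
    """A virtual dog with self-consistent ground truth for every segment."""

    seed: int
    body_mass: float
    segments: Mapping[str, SyntheticSegment]
    morphometrics: MorphometricRecord

    def ground_truth(self, key: str) -> SyntheticSegment:
        return self.segments[key]


def _bounding_extents(solid: GeometricSolid) -> tuple[float, float, float]:
    d = solid.dimensions
    if solid.shape == "cylinder":
        return 2 * d["radius"], 2 * d["radius"], d["length"]
    if solid.shape == "cone":
        return 2 * d["radius"], 2 * d["radius"], d["length"]
    if solid.shape == "conical_frustum":
        r = max(d["r_proximal"], d["r_distal"])
        return 2 * r, 2 * r, d["length"]
    if solid.shape == "rectangular_pyramid":
        return d["base_a"], d["base_b"], d["length"]
    return 2 * d["semi_a"], 2 * d["semi_b"], 2 * d["semi_c"]


def _solid_for(name: str, mass: float, volume: float, length: float) -> GeometricSolid:
    """Build the assigned solid matching a target volume and length."""
    shape = SEGMENT_SHAPES[name]
    if shape == "cylinder":
        r = np.sqrt(volume / (np.pi * length))
        dims = {"radius": r, "length": length}
    elif shape == "cone":
        r = np.sqrt(3.0 * volume / (np.pi * length))
        dims = {"radius": r, "length": length}
    elif shape == "conical_frustum":
        t = _TAPER[name]
        r_p = np.sqrt(3.0 * volume / (np.pi * length * (1.0 + t + t * t)))
        dims = {"r_proximal": r_p, "r_distal": t * r_p, "length": length}
    elif shape == "rectangular_pyramid":
        a = np.sqrt(3.0 * volume / (_PES_ASPECT * length))
        dims = {"base_a": a, "base_b": _PES_ASPECT * a, "length": length}
    else:  # ellipsoid
        sc = length / 2.0
        sa = np.sqrt(3.0 * volume / (4.0 * np.pi * sc * _HEAD_ASPECT))
        dims = {"semi_a": sa, "semi_b": _HEAD_ASPECT * sa, "semi_c": sc}
    return GeometricSolid(shape=shape, dimensions=dims, mass=mass)


def _dimensions_record(name: str, solid: GeometricSolid) -> dict[str, float]:
    """Morphometric dimensions implied by the generating solid."""
    d = solid.dimensions
    circ = lambda r: 2.0 * np.pi * r
    if name in ("manus", "antebrachium", "crus"):
        return {f"{name}.b": d["length"], f"{name}.c": circ(d["radius"])}
    if name == "brachium":
        return {
            "brachium.b": d["length"],
            "brachium.c": circ(d["r_proximal"]),
            "brachium.d": circ(d["r_distal"]),
        }
    if name == "thigh":
        return {"thigh.b": d["length"], "thigh.c": circ(d["r_distal"])}
    if name == "pes":
        return {"pes.b": d["length"], "pes.c": d["base_a"], "pes.d": d["base_b"]}
    if name == "head":
        return {"head.b": 2.0 * d["semi_c"], "head.c": 2.0 * d["semi_a"]}
    if name == "neck":
        r_mid = 0.5 * (d["r_proximal"] + d["r_distal"])
        return {
            "neck.b": d["length"],
            "neck.c": circ(d["r_proximal"]),
            "neck.d": circ(r_mid),
            "neck.e": circ(d["r_distal"]),
        }
    if name == "abdomen":
        return {
            "abdomen.b": circ(d["r_proximal"]),
            "abdomen.c": d["length"],
            "abdomen.d": circ(d["r_distal"]),
        }
    if name == "thorax":
        return {
            "thorax.b": circ(d["r_proximal"]),
            "thorax.c": d["length"],
            "thorax.d": circ(d["r_distal"]),
        }
    return {"tail.b": d["length"], "tail.c": circ(d["radius"])}


def nominal_dimensions(name: str) -> dict[str, float]:
    """Dispersion-free morphometric dimensions of a reference segment."""
    ref, _ = lookup(name)
    mass = ref.mass_fraction * reference_dog().body_mass
    solid = _solid_for(name, mass, ref.volume_m3, ref.l_ref)
    return _dimensions_record(name, solid)


def generate_dog(spec: CohortSpec | None = None, seed: int = 0) -> SyntheticDog:
    """One reproducible virtual dog.

    Body mass is drawn uniformly over the cohort range; each of the 17
    segments draws its mass fraction (lognormal around the reference
    fraction at the packaged CV), density and length, then fractions are
    renormalised so segment masses sum to the body mass exactly.  Segment
    solids match the drawn mass, volume and length; the morphometric
    record is derived from the left-side solids plus the axial segments.
    """
    spec = spec or CohortSpec()
    body_rng = _rng(seed, _BODY_STREAM)
    lo, hi = spec.body_mass_range
    body_mass = float(body_rng.uniform(lo, hi))

    draws = {}
    for key in _SEGMENT_KEYS:
        name = key.split("_")[-1]
        ref, _ = lookup(name)
        rng = _rng(seed, _segment_stream(key))
        frac_cv = spec.bsp_cv_scale * ref.mass_fraction_sd / ref.mass_fraction
        dens_cv = spec.bsp_cv_scale * ref.density_sd / ref.density
        frac = ref.mass_fraction * _lognormal(rng, frac_cv)
        density = ref.density * _lognormal(rng, dens_cv)
        length = ref.l_ref * _lognormal(rng, spec.dimension_cv)
        draws[key] = (name, frac, density, length)

    total_frac = sum(f for _, f, _, _ in draws.values())
    segments = {}
    for key, (name, frac, density, length) in draws.items():
        mass = frac / total_frac * body_mass
        volume = mass / density
        solid = _solid_for(name, mass, volume, length)
        m, com, tensor = solid_inertia(solid)
        segments[key] = SyntheticSegment(
            key=key, name=name, solid=solid, mass=m, com=com, tensor=tensor,
            dimensions=_dimensions_record(name, solid),
        )

    dims = {}
    for name in AXIAL_SEGMENTS:
        dims.update(segments[name].dimensions)
    for name in LIMB_SEGMENTS:
        dims.update(segments[f"left_{name}"].dimensions)
    record = MorphometricRecord(body_mass=body_mass, dimensions=dims,
                                dog_id=f"synthetic-{seed}")
    return SyntheticDog(seed=seed, body_mass=body_mass, segments=segments,
                        morphometrics=record)


def _lognormal(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


@dataclass(frozen=True)
class SegmentSession:
    """Six-axis pendulum trial set for one segment (traces + metadata)."""

    key: str
    m_s: float
    box: BoxCalibration
    theta: float
    g: float
    pivot_to_com: float
    composite_traces: Mapping[str, tuple[OscillationTrace, ...]]
    box_traces: Mapping[str, tuple[OscillationTrace, ...]]
    composite_mass: float
    balance_point: np.ndarray     # knife-edge balance of the composite, box frame
    true_tensor: InertiaTensor | None = None  # segment tensor in box axes (ground truth)


@dataclass(frozen=True)
class PendulumSession:
    seed: int
    spec: BoxSpec
    segments: Mapping[str, SegmentSession]


def _shm_trace(period: float, spec: BoxSpec, rng: np.random.Generator,
               noise: float) -> OscillationTrace:
    n = int(np.ceil(spec.n_cycles * period * spec.sample_rate)) + 1
    t = np.arange(n) / spec.sample_rate
    phase = rng.uniform(0.0, 2.0 * np.pi)
    x = spec.amplitude * np.cos(2.0 * np.pi * t / period + phase)
    if noise > 0:
        x = x + rng.normal(0.0, noise * spec.amplitude, size=n)
    return OscillationTrace(sample_rate=spec.sample_rate, samples=x)


def generate_pendulum_session(
    dog: SyntheticDog,
    spec: BoxSpec | None = None,
    noise: float = 0.0,
    seed: int = 0,
    segment_keys: Sequence[str] | None = None,
) -> PendulumSession:
    """Forward-simulate six-axis pendulum trials for a dog's segments.

    Each segment sits centred in its Styrofoam holder (segment CoM at the
    box CoM), so one pivot-to-CoM length serves every hang orientation;
    the segment's long axis is tilted by a random rotation of up to
    ``spec.misalignment_deg`` relative to the box axes, which is what
    produces nonzero products of inertia in the box frame.  For each
    axis u the composite and empty-box periods follow the
    compound-pendulum relation with I_pivot = uᵀIu + m l²; traces are
    SHM plus Gaussian noise at ``noise`` × amplitude.  Each
    :class:`SegmentSession` records the box-frame ground-truth tensor for
    recovery tests.
    """
    spec = spec or BoxSpec()
    keys = tuple(segment_keys) if segment_keys is not None else _SEGMENT_KEYS
    sessions = {}
    for key in keys:
        seg = dog.segments[key]
        rng = _rng(seed, 2000 + _segment_stream(key))
        true_tensor = _random_tilt(seg.tensor, spec.misalignment_deg, rng)
        ex, ey, ez = _bounding_extents(seg.solid)
        bx, by, bz = (spec.padding * e for e in (ex, ey, ez))
        box_mass = spec.foam_density * bx * by * bz
        box_tensor = cuboid_inertia(box_mass, bx, by, bz)
        box_com = np.array([bx / 2.0, by / 2.0, bz / 2.0])  # box-frame origin at a corner
        box = BoxCalibration(mass=box_mass, com=box_com, tensor=box_tensor)

        comp_mass = box_mass + seg.mass
        comp_tensor = InertiaTensor.from_matrix(
            box_tensor.matrix() + true_tensor.matrix(), frame_point="com",
        )
        if spec.pendulum_length is not None:
            l = spec.pendulum_length
        else:
            l = max(spec.min_pendulum_length, spec.hang_factor * max(bx, by, bz))
        comp_traces, box_traces = {}, {}
        for axis in list(AXES) + list(SKEW_PAIRS):
            u = AXES[axis] if axis in AXES else skew_axis_vector(axis, spec.theta)
            i_comp = moi_about_axis(comp_tensor, u) + comp_mass * l * l
            i_box = moi_about_axis(box_tensor, u) + box_mass * l * l
            t_comp = 2.0 * np.pi * np.sqrt(i_comp / (comp_mass * spec.g * l))
            t_box = 2.0 * np.pi * np.sqrt(i_box / (box_mass * spec.g * l))
            comp_traces[axis] = tuple(
                _shm_trace(t_comp, spec, rng, noise)
                for _ in range(spec.trials_per_axis)
            )
            box_traces[axis] = tuple(
                _shm_trace(t_box, spec, rng, noise)
                for _ in range(spec.trials_per_axis)
            )
        sessions[key] = SegmentSession(
            key=key, m_s=seg.mass, box=box, theta=spec.theta, g=spec.g,
            pivot_to_com=l, composite_traces=comp_traces, box_traces=box_traces,
            composite_mass=comp_mass, balance_point=box_com.copy(),
            true_tensor=true_tensor,
        )
    return PendulumSession(seed=seed, spec=spec, segments=sessions)


def _random_tilt(tensor: InertiaTensor, max_deg: float,
                 rng: np.random.Generator) -> InertiaTensor:
    """Rotate a tensor by a random axis-angle tilt of at most ``max_deg``."""
    if max_deg <= 0:
        return tensor
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    R = np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)
    return InertiaTensor.from_matrix(
        R @ tensor.matrix() @ R.T, frame_point="com", axes_label="box axes",
    )


def invert_session(session: SegmentSession) -> InertiaTensor:
    """Run the full measurement pipeline on one segment's session.

    estimate_period (mean over the successive trials of each axis) ->
    PendulumTrial -> segment MoI per axis -> products from the skew
    axes, reconstructing the 6-component tensor about the segment CoM in
    box axes.
    """
    trials = {}
    for axis in session.composite_traces:
        t_c = float(np.mean([estimate_period(tr)
                             for tr in session.composite_traces[axis]]))
        t_b = float(np.mean([estimate_period(tr)
                             for tr in session.box_traces[axis]]))
        trials[axis] = (
            PendulumTrial(session.composite_mass, session.pivot_to_com, t_c,
                          "composite"),
            PendulumTrial(session.box.mass, session.pivot_to_com, t_b,
                          "empty_box"),
        )
    return extract_segment_tensor(
        trials, m_s=session.m_s, l_s=session.pivot_to_com,
        theta=session.theta, g=session.g,
    )


def generate_cohort(
    spec: CohortSpec | None = None,
) -> list[tuple[MorphometricRecord, dict[str, dict[str, float]]]]:
    """A cohort of virtual dogs with ground-truth BSPs per segment name.

    Each entry pairs the dog's morphometric record with
    ``{segment: {"mass": kg, "i_xx": ..., "i_yy": ..., "i_zz": ...}}``
    (left-side ground truth for limb segments, solid symmetry frame),
    perturbed by the spec's relative measurement noise.
    """
    spec = spec or CohortSpec()
    out = []
    for i in range(spec.n):
        dog = generate_dog(spec, seed=_subseed(spec.seed, i))
        noise_rng = _rng(_subseed(spec.seed, i), 3000)
        gt = {}
        for name in SEGMENT_NAMES:
            key = name if name in AXIAL_SEGMENTS else f"left_{name}"
            seg = dog.segments[key]
            vals = {
                "mass": seg.mass,
                "i_xx": seg.tensor.i_xx,
                "i_yy": seg.tensor.i_yy,
                "i_zz": seg.tensor.i_zz,
            }
            if spec.measurement_noise > 0:
                vals = {
                    k: v * (1.0 + noise_rng.normal(0.0, spec.measurement_noise))
                    for k, v in vals.items()
                }
            gt[name] = vals
        out.append((dog.morphometrics, gt))
    return out


def _subseed(seed: int, i: int) -> int:
    return int(np.random.SeedSequence(entropy=(seed, 4000 + i)).generate_state(1)[0]
               % (2**31 - 1))


def generate_cohort_from_equation(
    eq: RegressionEquation,
    spec: CohortSpec | None = None,
    noise_cv: float = 0.01,
) -> tuple[list[tuple[MorphometricRecord, float]], np.ndarray]:
    """Cohort whose observed values come from a published equation.

    Dimensions scatter lognormally around the reference segment's nominal
    values; the observed quantity is the equation's literal value plus
    Gaussian noise of ``noise_cv`` × the cohort-mean magnitude.  Returns
    the cohort and the generating coefficient vector
    (a_coef, [term_coef], intercept) for recovery tests.
    """
    spec = spec or CohortSpec()
    nominal = nominal_dimensions(eq.segment)
    rng = _rng(spec.seed, 5000)
    cohort_dims = []
    values = []
    for i in range(spec.n):
        body_mass = float(rng.uniform(*spec.body_mass_range))
        dims = {k: v * _lognormal(rng, spec.dimension_cv) for k, v in nominal.items()}
        rec = MorphometricRecord(body_mass=body_mass, dimensions=dims,
                                 dog_id=f"eq-cohort-{i}")
        value = eq.a_coef * body_mass + eq.intercept
        if eq.term_kind != "mass_only":
            g = build_term(eq.term_kind,
                           [dims[f"{eq.segment}.{k}"] for k in eq.dimension_keys])
            if eq.geometry_times_mass:
                g *= body_mass
            value += eq.term_coef * g
        cohort_dims.append(rec)
        values.append(value)
    scale = float(np.mean(np.abs(values))) or 1.0
    observed = [
        v + rng.normal(0.0, noise_cv * scale) if noise_cv > 0 else v
        for v in values
    ]
    cohort = list(zip(cohort_dims, observed))
    if eq.term_kind == "mass_only":
        beta = np.array([eq.a_coef, eq.intercept])
    else:
        beta = np.array([eq.a_coef, eq.term_coef, eq.intercept])
    return cohort, beta
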