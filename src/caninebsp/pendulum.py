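"""Compound-pendulum extraction of segment inertial properties.

A frozen segment is strapped inside a Styrofoam holder box marked with six
axes (xx, yy, zz plus three coplanar skew axes xy, xz, yz) and swung as a
small-amplitude compound pendulum about each axis, with and without the
segment in situ.  From the oscillation period, pendulum length and mass,
the moment of inertia about the pivot follows from

    T = 2π sqrt(I_pivot / (m g l))   =>   I_pivot = m g l T² / (4π²),

the empty-box contribution is subtracted, and the parallel-axis term
``m_s l_s²`` removes the pivot offset, leaving the segment's moment about
its own centre of mass.  The three skew-axis moments then yield the
products of inertia, and knife-edge balance points yield the CoM by
moment balance.  This module implements each of those steps plus a
six-axis driver that reconstructs the full symmetric tensor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inertial_math import InertiaTensor

__all__ = [
    "PendulumTrial",
    "OscillationTrace",
    "BoxCalibration",
    "SkewAxisMeasurement",
    "InsufficientCyclesError",
    "MeasurementWarning",
    "estimate_period",
    "pivot_moi",
    "segment_com_moi",
    "product_moi",
    "com_from_balance",
    "average_masses",
    "extract_segment_tensor",
    "SKEW_PAIRS",
    "skew_axis_vector",
    "AXES",
]

#: unit vectors of the three primary box axes
AXES: Mapping[str, np.ndarray] = {
    "xx": np.array([1.0, 0.0, 0.0]),
    "yy": np.array([0.0, 1.0, 0.0]),
    "zz": np.array([0.0, 0.0, 1.0]),
}

#: skew-axis label -> (first axis a, second axis b); the skew axis lies in
#: the ab-plane at angle theta from the b axis toward a
SKEW_PAIRS: Mapping[str, tuple[str, str]] = {
    "xy": ("x", "y"),
    "xz": ("x", "z"),
    "yz": ("y", "z"),
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class InsufficientCyclesError(ValueError):
    """Trace does not contain enough full oscillation cycles."""


class MeasurementWarning(UserWarning):
    """Physically suspect but recoverable measurement (e.g. negative MoI)."""


@dataclass(frozen=True)
class PendulumTrial:
    """One pendulum measurement: suspended mass, pivot-to-CoM length, period."""

    mass: float          # kg
    pivot_to_com: float  # m
    period: float        # s
    label: str = "composite"  # "composite" or "empty_box"

    def __post_init__(self):
        if not (self.mass > 0 and self.pivot_to_com > 0 and self.period > 0):
            raise ValueError("mass, pivot_to_com and period must all be > 0")
        if self.label not in ("composite", "empty_box"):
            raise ValueError(f"unknown trial label {self.label!r}")


@dataclass(frozen=True)
class OscillationTrace:
    """Uniformly sampled displacement record of a swinging box."""

    sample_rate: float            # Hz
    samples: np.ndarray           # displacement, arbitrary units

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 4:
            raise ValueError("samples must be a 1-D array with >= 4 points")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class BoxCalibration:
    """Known mechanical properties of an empty segment-holder box."""

    mass: float                 # kg
    com: np.ndarray             # m, in box frame
    tensor: InertiaTensor       # about the box CoM, box axes

    def __post_init__(self):
        object.__setattr__(self, "com", np.asarray(self.com, dtype=float))
        if self.mass <= 0:
            raise ValueError("box mass must be > 0")
        if self.com.shape != (3,):
            raise ValueError("box com must be a 3-vector")
        bad = self.tensor.triangle_violations()
        if bad:
            raise ValueError(f"box calibration tensor is unphysical: {bad}")


@dataclass(frozen=True)
class SkewAxisMeasurement:
    """Moments needed to recover one product of inertia.

    ``i_star`` is the moment about the skew axis that lies in the plane of
    the two primary axes, at angle ``theta`` (rad) from the second axis of
    the pair (e.g. from yy for the xy pair).  All three moments must refer
    to axes through one common point.
    """

    i_aa: float
    i_bb: float
    i_star: float
    theta: float

    def __post_init__(self):
        if not 0.0 < self.theta < np.pi / 2.0:
            raise ValueError("theta must lie strictly between 0 and pi/2")


def skew_axis_vector(pair: str, theta: float) -> np.ndarray:
    """Unit vector of the skew axis for an axis pair at angle theta from b."""
    a, b = SKEW_PAIRS[pair]
    u = np.zeros(3)
    u[_AXIS_INDEX[a]] = np.sin(theta)
    u[_AXIS_INDEX[b]] = np.cos(theta)
    return u


def _crossing_times(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """All zero-crossing times (either direction), linearly interpolated."""
    s = np.sign(x)
    # treat exact zeros as belonging to the following sign
    s[s == 0] = 1
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0]
    if idx.size == 0:
        return np.empty(0)
    x0, x1 = x[idx], x[idx + 1]
    frac = x0 / (x0 - x1)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def _cluster(times: np.ndarray) -> np.ndarray:
    """Merge bursts of crossings produced by noise near a true crossing.

    True crossings are half a period apart, so the largest inter-crossing
    gap is ~T/2; gaps below 30 % of it are jitter inside one crossing.
    Each burst is replaced by its mean time.
    """
    if times.size <= 2:
        return times
    gaps = np.diff(times)
    thr = 0.3 * gaps.max()
    groups = np.concatenate([[0], np.cumsum(gaps > thr)])
    return np.array([times[groups == g].mean() for g in range(groups[-1] + 1)])


def _crossing_slope(times: np.ndarray) -> float:
    """Half-period from crossing times by least squares.

    Crossings sit nominally at t_k = t_0 + k·T/2; the half-cycle index k
    is recovered by rounding against the median gap (robust to an
    occasional missed crossing) and the slope of t against k is T/2,
    using every crossing rather than just the endpoints.
    """
    gaps = np.diff(times)
    gap = np.median(gaps)
    k = np.round((times - times[0]) / gap)
    return float(np.polyfit(k, times, 1)[0])


def _sinusoid_refine(t: np.ndarray, x: np.ndarray, period0: float) -> float:
    """Refine a period estimate by a full sinusoid least-squares fit.

    For a trial frequency the amplitude, phase and offset enter linearly,
    so the fit reduces to a 1-D search over angular frequency (bracketed
    around the zero-crossing estimate) of the linear-least-squares
    residual.  Uses every sample, which for a noisy trace is far more
    precise than crossing times alone.
    """
    from scipy.optimize import minimize_scalar

    def sse(omega: float) -> float:
        design = np.column_stack(
            [np.cos(omega * t), np.sin(omega * t), np.ones_like(t)]
        )
        _, res, _, _ = np.linalg.lstsq(design, x, rcond=None)
        if res.size:
            return float(res[0])
        return float(((design @ np.linalg.lstsq(design, x, rcond=None)[0] - x) ** 2).sum())

    w0 = 2.0 * np.pi / period0
    result = minimize_scalar(sse, bounds=(0.95 * w0, 1.05 * w0), method="bounded",
                             options={"xatol": 1e-10 * w0})
    return float(2.0 * np.pi / result.x)


def estimate_period(
    trace: OscillationTrace, min_cycles: int = 3, refine: bool = True
) -> float:
    """Oscillation period of a pendulum trace.

    The mean-removed signal's zero crossings are located by linear
    interpolation between samples (noise bursts near a crossing are
    collapsed to their mean time); consecutive crossings are half a
    period apart, so twice their least-squares spacing gives the initial
    period.  With ``refine`` (default) the estimate is polished by a
    whole-trace sinusoid fit, which suppresses crossing-time jitter.
    Raises :class:`InsufficientCyclesError` below ``min_cycles`` full
    cycles.
    """
    x = trace.samples - trace.samples.mean()
    if np.allclose(x, 0.0):
        raise InsufficientCyclesError("constant signal has no oscillation")
    t = trace.times
    crossings = _cluster(_crossing_times(t, x))
    if crossings.size < 2 * min_cycles + 1:
        raise InsufficientCyclesError(
            f"found {max((crossings.size - 1) // 2, 0)} full cycles; "
            f"need >= {min_cycles}"
        )
    period = 2.0 * _crossing_slope(crossings)
    if refine:
        period = _sinusoid_refine(t, x, period)
    return period


def pivot_moi(m: float, l: float, T: float, g: float = 9.81) -> float:
    """Compound-pendulum moment of inertia about the pivot: m·g·l·T²/(4π²)."""
    if min(m, l, T, g) <= 0:
        raise ValueError("m, l, T and g must all be > 0")
    return m * g * l * T * T / (4.0 * np.pi * np.pi)


def segment_com_moi(
    composite: PendulumTrial,
    box: PendulumTrial,
    m_s: float,
    l_s: float,
    g: float = 9.81,
    mass_tol: float = 0.01,
    negative_tol: float = 1e-9,
) -> float:
    """Segment MoI about its CoM from a composite and an empty-box trial.

    ``(m_c g l_c T_c² − m_b g l_b T_b²)/(4π²) − m_s l_s²`` where ``l_s``
    is the pivot-to-segment-CoM distance.  A negative result (physically
    impossible, but present in real measured data) is returned as-is with
    a :class:`MeasurementWarning`.
    """
    if m_s < 0 or l_s < 0:
        raise ValueError("m_s and l_s must be >= 0")
    expected = composite.mass - box.mass
    if abs(expected - m_s) > mass_tol * max(m_s, 1e-12) + 1e-12:
        warnings.warn(
            f"m_s={m_s:.6g} differs from composite-box mass {expected:.6g}",
            MeasurementWarning, stacklevel=2,
        )
    i = (
        pivot_moi(composite.mass, composite.pivot_to_com, composite.period, g)
        - pivot_moi(box.mass, box.pivot_to_com, box.period, g)
        - m_s * l_s * l_s
    )
    if i < -negative_tol:
        warnings.warn(
            f"extracted MoI {i:.3e} kg.m2 is negative (measurement inconsistency)",
            MeasurementWarning, stacklevel=2,
        )
    return i


def product_moi(meas: SkewAxisMeasurement, cond_tol: float = 1e-6) -> float:
    """Product of inertia from a coplanar skew-axis moment.

    ``P = [I_bb + I_aa tan²θ − (1 + tan²θ) I*] / (2 tanθ)``, the exact
    algebraic inverse of the quadratic form
    ``I* = I_aa sin²θ + I_bb cos²θ − 2 P sinθ cosθ``.
    """
    theta = meas.theta
    if theta < cond_tol or theta > np.pi / 2.0 - cond_tol:
        raise ValueError(f"theta={theta:.3g} rad is ill-conditioned")
    t = np.tan(theta)
    return (meas.i_bb + meas.i_aa * t * t - (1.0 + t * t) * meas.i_star) / (2.0 * t)


def com_from_balance(
    composite_balance, box: BoxCalibration, m_s: float
) -> np.ndarray:
    """Segment CoM from knife-edge balance points of the composite box.

    Per axis: ``x_s = (m_c x_c − m_b x_b) / m_s`` with the composite mass
    ``m_c = m_s + m_b``.
    """
    if m_s <= 0:
        raise ValueError("m_s must be > 0")
    x_c = np.asarray(composite_balance, dtype=float)
    if x_c.shape != (3,):
        raise ValueError("composite balance must be a 3-vector")
    m_c = m_s + box.mass
    return (m_c * x_c - box.mass * box.com) / m_s


def average_masses(
    m1: float, m2: float, m3: float, spread_threshold: float = 0.05
) -> tuple[float, float]:
    """Mean of the three repeated mass measures plus their relative spread.

    Masses are weighed three times over about a week to monitor
    sublimation loss; the mean feeds the inertial calculations.  Returns
    ``(mean, spread)`` with spread = (max−min)/mean; a spread beyond
    ``spread_threshold`` raises a :class:`MeasurementWarning`.
    """
    ms = np.array([m1, m2, m3], dtype=float)
    if np.any(ms <= 0):
        raise ValueError("all three masses must be > 0")
    mean = float(ms.mean())
    spread = float((ms.max() - ms.min()) / mean)
    if spread > spread_threshold:
        warnings.warn(
            f"mass spread {spread:.1%} exceeds {spread_threshold:.1%} "
            "(possible sublimation or weighing error)",
            MeasurementWarning, stacklevel=2,
        )
    return mean, spread


def extract_segment_tensor(
    trials: Mapping[str, tuple[PendulumTrial, PendulumTrial]],
    m_s: float,
    l_s: float | Mapping[str, float],
    theta: float = np.pi / 4.0,
    g: float = 9.81,
) -> InertiaTensor:
    """Reconstruct the full 6-component segment tensor from six-axis trials.

    ``trials`` maps each axis label (xx, yy, zz, xy, xz, yz) to its
    (composite, empty-box) trial pair; ``l_s`` is the pivot-to-segment-CoM
    distance, either one number or per-axis.  The three primary axes give
    the diagonal directly; each skew axis at angle ``theta`` from the
    second axis of its pair gives one product via :func:`product_moi`.
    """
    needed = set(AXES) | set(SKEW_PAIRS)
    missing = sorted(needed - set(trials))
    if missing:
        raise ValueError(f"missing trials for axes: {missing}")

    def ls(axis: str) -> float:
        return l_s[axis] if isinstance(l_s, Mapping) else float(l_s)

    moi = {
        axis: segment_com_moi(comp, box, m_s, ls(axis), g)
        for axis, (comp, box) in trials.items()
    }
    products = {}
    for pair, (a, b) in SKEW_PAIRS.items():
        meas = SkewAxisMeasurement(
            i_aa=moi[a + a], i_bb=moi[b + b], i_star=moi[pair], theta=theta
        )
        products["p_" + pair] = product_moi(meas)
    return InertiaTensor(
        i_xx=moi["xx"], i_yy=moi["yy"], i_zz=moi["zz"],
        frame_point="com", axes_label="box axes at segment CoM", **products,
    )
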