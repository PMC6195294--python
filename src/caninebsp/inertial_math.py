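"""Rigid-body inertia arithmetic for homogeneous geometric solids.

Segments of the dog are modelled as one of five homogeneous solids --
cylinder, rectangular pyramid, cone, conical frustum, ellipsoid -- each
aligned with its long (proximal-to-distal) axis on ``z``, proximal end at
``z = 0``.  This module provides closed-form masses, centres of mass and
inertia tensors for those solids, the parallel-axis transform, the
moment of inertia about an arbitrary axis, and a deterministic voxel
integrator used as an independent numerical oracle.

Sign convention
---------------
Products of inertia are stored in the mass-integral form
``P_ab = ∫ a·b dm``; the off-diagonals of the inertia *matrix* are
``-P_ab``.  ``moi_about_axis`` evaluates the quadratic form on that
matrix, which makes the skew-axis product-recovery formula in
:mod:`caninebsp.pendulum` an exact algebraic inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "InertiaTensor",
    "GeometricSolid",
    "InvalidGeometryError",
    "SHAPES",
    "solid_inertia",
    "numeric_inertia",
    "parallel_axis",
    "moi_about_axis",
    "cuboid_inertia",
]

SHAPES = ("cylinder", "rectangular_pyramid", "cone", "conical_frustum", "ellipsoid")

#: required dimension keys per shape, all metres, all > 0
_SHAPE_DIMS: Mapping[str, tuple[str, ...]] = {
    "cylinder": ("radius", "length"),
    "rectangular_pyramid": ("base_a", "base_b", "length"),
    "cone": ("radius", "length"),
    "conical_frustum": ("r_proximal", "r_distal", "length"),
    "ellipsoid": ("semi_a", "semi_b", "semi_c"),
}


class InvalidGeometryError(ValueError):
    """Raised for non-positive dimensions or an unknown shape."""


@dataclass(frozen=True)
class InertiaTensor:
    """Symmetric second-moment description about stated axes at a stated point.

    Moments ``i_aa`` are ``∫ (b² + c²) dm`` and products ``p_ab`` are
    ``∫ a·b dm`` (kg·m²).  ``frame_point`` records the point the axes pass
    through (``com``, ``pivot`` or ``box_origin``).
    """

    i_xx: float
    i_yy: float
    i_zz: float
    p_xy: float = 0.0
    p_xz: float = 0.0
    p_yz: float = 0.0
    frame_point: str = "com"
    axes_label: str = ""

    def matrix(self) -> np.ndarray:
        """Inertia matrix with off-diagonals ``-p_ab``."""
        return np.array(
            [
                [self.i_xx, -self.p_xy, -self.p_xz],
                [-self.p_xy, self.i_yy, -self.p_yz],
                [-self.p_xz, -self.p_yz, self.i_zz],
            ]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray, **kwargs) -> "InertiaTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T, rtol=1e-8, atol=1e-12):
            raise ValueError("inertia matrix must be symmetric 3x3")
        return cls(
            i_xx=float(m[0, 0]), i_yy=float(m[1, 1]), i_zz=float(m[2, 2]),
            p_xy=float(-m[0, 1]), p_xz=float(-m[0, 2]), p_yz=float(-m[1, 2]),
            **kwargs,
        )

    def diagonal(self) -> np.ndarray:
        return np.array([self.i_xx, self.i_yy, self.i_zz])

    def products(self) -> np.ndarray:
        return np.array([self.p_xy, self.p_xz, self.p_yz])

    def triangle_violations(self, rtol: float = 1e-9) -> list[str]:
        """Perpendicular-axis-type inequality audit.

        For any real mass distribution ``I_aa + I_bb >= I_cc`` for every
        cyclic permutation.  Returns the violated permutations (empty list
        means physically consistent); never raises, because measured data
        can legitimately fail this check.
        """
        d = {"xx": self.i_xx, "yy": self.i_yy, "zz": self.i_zz}
        out = []
        for a, b, c in (("xx", "yy", "zz"), ("yy", "zz", "xx"), ("zz", "xx", "yy")):
            if d[a] + d[b] < d[c] * (1.0 - rtol):
                out.append(f"{a}+{b}<{c}")
        return out


@dataclass(frozen=True)
class GeometricSolid:
    """A homogeneous solid with its long axis on z, proximal end at z = 0.

    Exactly one of ``density`` (kg/m³) or ``mass`` (kg) must be given; the
    other is derived from the analytic volume.
    """

    shape: str
    dimensions: Mapping[str, float]
    density: float | None = None
    mass: float | None = None

    def __post_init__(self):
        if self.shape not in _SHAPE_DIMS:
            raise InvalidGeometryError(f"unknown shape {self.shape!r}")
        required = _SHAPE_DIMS[self.shape]
        missing = [k for k in required if k not in self.dimensions]
        if missing:
            raise InvalidGeometryError(f"{self.shape}: missing dimensions {missing}")
        for k in required:
            if not self.dimensions[k] > 0:
                raise InvalidGeometryError(
                    f"{self.shape}: dimension {k}={self.dimensions[k]} must be > 0"
                )
        if (self.density is None) == (self.mass is None):
            raise InvalidGeometryError("specify exactly one of density or mass")
        if self.density is not None and not self.density > 0:
            raise InvalidGeometryError("density must be > 0")
        if self.mass is not None and not self.mass > 0:
            raise InvalidGeometryError("mass must be > 0")

    @property
    def volume(self) -> float:
        d = self.dimensions
        if self.shape == "cylinder":
            return np.pi * d["radius"] ** 2 * d["length"]
        if self.shape == "cone":
            return np.pi * d["radius"] ** 2 * d["length"] / 3.0
        if self.shape == "conical_frustum":
            r0, r1 = d["r_proximal"], d["r_distal"]
            return np.pi * d["length"] * (r0 * r0 + r0 * r1 + r1 * r1) / 3.0
        if self.shape == "rectangular_pyramid":
            return d["base_a"] * d["base_b"] * d["length"] / 3.0
        return 4.0 / 3.0 * np.pi * d["semi_a"] * d["semi_b"] * d["semi_c"]

    def mass_density(self) -> tuple[float, float]:
        """(mass, density), deriving the unspecified one from the volume."""
        v = self.volume
        if self.density is not None:
            return self.density * v, self.density
        return self.mass, self.mass / v


def _axisymmetric_tensor(r0: float, r1: float, h: float, rho: float):
    """Closed-form CoM tensor for a solid with radius r(z)=r0+(r1-r0)z/h.

    Covers cylinder (r0=r1), cone (r1=0) and conical frustum.  Uses exact
    polynomial integration of the stacked-disc integrals:
    ``I_zz = ρ∫ (π/2) r⁴ dz`` and
    ``I_xx = ρ∫ [(π/4) r⁴ + π r² (z - z̄)²] dz``.
    """
    slope = (r1 - r0) / h
    r = np.polynomial.Polynomial([r0, slope])
    r2 = r * r
    r4 = r2 * r2
    A = np.pi * r2

    def integ(p):
        q = p.integ()
        return q(h) - q(0.0)

    V = integ(A)
    z_com = integ(A * np.polynomial.Polynomial([0.0, 1.0])) / V
    mass = rho * V
    i_zz = rho * integ(np.pi / 2.0 * r4)
    dz = np.polynomial.Polynomial([-z_com, 1.0])
    i_xx = rho * integ(np.pi / 4.0 * r4 + A * dz * dz)
    return mass, z_com, i_xx, i_xx, i_zz


def _pyramid_tensor(a: float, b: float, h: float, rho: float):
    """Closed-form CoM tensor for a rectangular pyramid, base a×b at z=0.

    Slab at z is a rectangle a·s × b·s with s = 1 - z/h.  Standard result:
    CoM at h/4, I_xx = m(b²/20 + 3h²/80), I_yy = m(a²/20 + 3h²/80),
    I_zz = m(a² + b²)/20.
    """
    V = a * b * h / 3.0
    mass = rho * V
    z_com = h / 4.0
    i_xx = mass * (b * b / 20.0 + 3.0 * h * h / 80.0)
    i_yy = mass * (a * a / 20.0 + 3.0 * h * h / 80.0)
    i_zz = mass * (a * a + b * b) / 20.0
    return mass, z_com, i_xx, i_yy, i_zz


def solid_inertia(solid: GeometricSolid) -> tuple[float, np.ndarray, InertiaTensor]:
    """Mass, centre of mass and closed-form inertia tensor about the CoM.

    The tensor is diagonal in the solid's symmetry frame (long axis z).
    The CoM lies on the z axis; its z coordinate is measured from the
    proximal end (z = 0).
    """
    mass, rho = solid.mass_density()
    d = solid.dimensions
    if solid.shape == "cylinder":
        r, h = d["radius"], d["length"]
        i_zz = 0.5 * mass * r * r
        i_xx = mass * (3.0 * r * r + h * h) / 12.0
        com_z, i_yy = h / 2.0, i_xx
    elif solid.shape == "cone":
        _, com_z, i_xx, i_yy, i_zz = _axisymmetric_tensor(d["radius"], 0.0, d["length"], rho)
    elif solid.shape == "conical_frustum":
        _, com_z, i_xx, i_yy, i_zz = _axisymmetric_tensor(
            d["r_proximal"], d["r_distal"], d["length"], rho
        )
    elif solid.shape == "rectangular_pyramid":
        _, com_z, i_xx, i_yy, i_zz = _pyramid_tensor(
            d["base_a"], d["base_b"], d["length"], rho
        )
    else:  # ellipsoid, centred: shift so proximal pole is z=0
        sa, sb, sc = d["semi_a"], d["semi_b"], d["semi_c"]
        i_xx = mass * (sb * sb + sc * sc) / 5.0
        i_yy = mass * (sa * sa + sc * sc) / 5.0
        i_zz = mass * (sa * sa + sb * sb) / 5.0
        com_z = sc  # long axis on z, proximal pole at z = 0
    com = np.array([0.0, 0.0, com_z])
    tensor = InertiaTensor(i_xx, i_yy, i_zz, frame_point="com",
                           axes_label=f"{solid.shape} symmetry frame")
    return mass, com, tensor


def _voxel_indicator(solid: GeometricSolid, x, y, z):
    d = solid.dimensions
    if solid.shape == "cylinder":
        return (x * x + y * y <= d["radius"] ** 2) & (z >= 0) & (z <= d["length"])
    if solid.shape in ("cone", "conical_frustum"):
        if solid.shape == "cone":
            r0, r1 = d["radius"], 0.0
        else:
            r0, r1 = d["r_proximal"], d["r_distal"]
        rz = r0 + (r1 - r0) * z / d["length"]
        return (x * x + y * y <= rz * rz) & (z >= 0) & (z <= d["length"])
    if solid.shape == "rectangular_pyramid":
        s = 1.0 - z / d["length"]
        return (
            (np.abs(x) <= d["base_a"] * s / 2.0)
            & (np.abs(y) <= d["base_b"] * s / 2.0)
            & (z >= 0) & (z <= d["length"])
        )
    zc = z - d["semi_c"]
    return (
        (x / d["semi_a"]) ** 2 + (y / d["semi_b"]) ** 2 + (zc / d["semi_c"]) ** 2
        <= 1.0
    )


def _bounds(solid: GeometricSolid):
    d = solid.dimensions
    if solid.shape == "cylinder":
        r = d["radius"]
        return (-r, r), (-r, r), (0.0, d["length"])
    if solid.shape == "cone":
        r = d["radius"]
        return (-r, r), (-r, r), (0.0, d["length"])
    if solid.shape == "conical_frustum":
        r = max(d["r_proximal"], d["r_distal"])
        return (-r, r), (-r, r), (0.0, d["length"])
    if solid.shape == "rectangular_pyramid":
        return (
            (-d["base_a"] / 2.0, d["base_a"] / 2.0),
            (-d["base_b"] / 2.0, d["base_b"] / 2.0),
            (0.0, d["length"]),
        )
    return (
        (-d["semi_a"], d["semi_a"]),
        (-d["semi_b"], d["semi_b"]),
        (0.0, 2.0 * d["semi_c"]),
    )


def numeric_inertia(
    solid: GeometricSolid, resolution: int = 200
) -> tuple[float, np.ndarray, InertiaTensor]:
    """Deterministic voxel-grid integration of the inertia integrals.

    A midpoint rule on a ``resolution³`` grid over the solid's bounding
    box.  Independent of :func:`solid_inertia` and used as its oracle;
    agreement is ~O(1/resolution²) for these convex shapes.  Density is
    taken from the analytic mass/volume so that mass convergence checks
    the integrated volume.
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50 per axis")
    mass_a, rho = solid.mass_density()
    (x0, x1), (y0, y1), (z0, z1) = _bounds(solid)
    n = resolution

    def centers(a, b):
        e = np.linspace(a, b, n + 1)
        return 0.5 * (e[:-1] + e[1:]), (b - a) / n

    x, dx = centers(x0, x1)
    y, dy = centers(y0, y1)
    z, dz = centers(z0, z1)
    ind = _voxel_indicator(
        solid, x[:, None, None], y[None, :, None], z[None, None, :]
    )
    # all sums reduce through 2-D marginals: cheap and exact
    m_xy = ind.sum(axis=2)
    m_xz = ind.sum(axis=1)
    m_yz = ind.sum(axis=0)
    n_x = m_xy.sum(axis=1).astype(float)
    n_y = m_xy.sum(axis=0).astype(float)
    n_z = m_xz.sum(axis=0).astype(float)
    count = n_x.sum()
    if count == 0:
        raise InvalidGeometryError("voxel grid found no interior points")
    dV = dx * dy * dz
    mass = rho * count * dV
    sx, sy, sz = (x * n_x).sum(), (y * n_y).sum(), (z * n_z).sum()
    cx, cy, cz = sx / count, sy / count, sz / count
    sxx, syy, szz = (x * x * n_x).sum(), (y * y * n_y).sum(), (z * z * n_z).sum()
    sxy = x @ m_xy @ y
    sxz = x @ m_xz @ z
    syz = y @ m_yz @ z
    # central second moments
    mxx = sxx - count * cx * cx
    myy = syy - count * cy * cy
    mzz = szz - count * cz * cz
    mxy = sxy - count * cx * cy
    mxz = sxz - count * cx * cz
    myz = syz - count * cy * cz
    k = rho * dV
    tensor = InertiaTensor(
        i_xx=k * (myy + mzz),
        i_yy=k * (mxx + mzz),
        i_zz=k * (mxx + myy),
        p_xy=k * mxy, p_xz=k * mxz, p_yz=k * myz,
        frame_point="com", axes_label="voxel grid",
    )
    return mass, np.array([cx, cy, cz]), tensor


def parallel_axis(
    tensor: InertiaTensor, mass: float, d, frame_point: str = "pivot"
) -> InertiaTensor:
    """Shift a CoM tensor to axes through a point displaced by ``d``.

    ``I'_aa = I_aa + m(|d|² - d_a²)`` and ``P'_ab = P_ab + m·d_a·d_b``.
    The displacement ``d`` points from the new reference point to the CoM
    (only squares and pairwise products enter, so the opposite convention
    gives the same result).  Calling again with ``-mass`` and the same
    ``d`` inverts the shift exactly.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (3,):
        raise ValueError("d must be a 3-vector")
    dx, dy, dz = d
    d2 = float(d @ d)
    return InertiaTensor(
        i_xx=tensor.i_xx + mass * (d2 - dx * dx),
        i_yy=tensor.i_yy + mass * (d2 - dy * dy),
        i_zz=tensor.i_zz + mass * (d2 - dz * dz),
        p_xy=tensor.p_xy + mass * dx * dy,
        p_xz=tensor.p_xz + mass * dx * dz,
        p_yz=tensor.p_yz + mass * dy * dz,
        frame_point=frame_point,
        axes_label=tensor.axes_label,
    )


def moi_about_axis(
    tensor: InertiaTensor, axis, on_non_unit: str = "error", tol: float = 1e-8
) -> float:
    """Moment of inertia about an arbitrary axis through the tensor's point.

    Evaluates the quadratic form ``uᵀ M u`` on the inertia matrix.  The
    axis must be a unit vector; ``on_non_unit`` selects whether a
    non-unit input raises (``"error"``) or is normalized with a warning
    (``"warn"``).
    """
    u = np.asarray(axis, dtype=float)
    if u.shape != (3,):
        raise ValueError("axis must be a 3-vector")
    norm = float(np.linalg.norm(u))
    if abs(norm - 1.0) > tol:
        if on_non_unit == "warn":
            warnings.warn(f"axis norm {norm:.6g} != 1; normalizing", stacklevel=2)
            u = u / norm
        else:
            raise ValueError(f"axis must be unit length (|axis| = {norm:.6g})")
    return float(u @ tensor.matrix() @ u)


def cuboid_inertia(mass: float, lx: float, ly: float, lz: float) -> InertiaTensor:
    """CoM tensor of a homogeneous rectangular box (used for segment holders)."""
    if min(mass, lx, ly, lz) <= 0:
        raise InvalidGeometryError("cuboid requires positive mass and edges")
    return InertiaTensor(
        i_xx=mass * (ly * ly + lz * lz) / 12.0,
        i_yy=mass * (lx * lx + lz * lz) / 12.0,
        i_zz=mass * (lx * lx + ly * ly) / 12.0,
        frame_point="com", axes_label="cuboid symmetry frame",
    )
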