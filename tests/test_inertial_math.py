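"""Closed-form solid tensors, the voxel oracle, and axis transforms."""

import numpy as np
import pytest

from caninebsp.inertial_math import (
    SHAPES,
    GeometricSolid,
    InertiaTensor,
    InvalidGeometryError,
    cuboid_inertia,
    moi_about_axis,
    numeric_inertia,
    parallel_axis,
    solid_inertia,
)
from conftest import random_solid, random_tensor


class TestClosedForms:
    def test_sphere_limit_of_ellipsoid(self):
        m0, r = 1.0, 0.1
        s = GeometricSolid("ellipsoid",
                           {"semi_a": r, "semi_b": r, "semi_c": r}, mass=m0)
        mass, com, t = solid_inertia(s)
        expected = 0.4 * m0 * r * r
        assert np.allclose(t.diagonal(), expected, rtol=1e-12)
        assert np.allclose(com, [0.0, 0.0, r])

    def test_cylinder_limit_of_frustum(self):
        r, h, m = 0.05, 0.3, 2.0
        s = GeometricSolid(
            "conical_frustum",
            {"r_proximal": r, "r_distal": r, "length": h}, mass=m,
        )
        _, com, t = solid_inertia(s)
        assert t.i_zz == pytest.approx(0.5 * m * r * r, rel=1e-12)
        assert t.i_xx == pytest.approx(m * (3 * r * r + h * h) / 12.0, rel=1e-12)
        assert com[2] == pytest.approx(h / 2.0)

    def test_cone_matches_standard_result(self):
        r, h = 0.05, 0.2
        s = GeometricSolid("cone", {"radius": r, "length": h}, density=1000.0)
        mass, com, t = solid_inertia(s)
        assert mass == pytest.approx(1000.0 * np.pi * r * r * h / 3.0, rel=1e-12)
        assert com[2] == pytest.approx(h / 4.0, rel=1e-12)
        assert t.i_zz == pytest.approx(0.3 * mass * r * r, rel=1e-12)
        assert t.i_xx == pytest.approx(3.0 / 20.0 * mass * (r * r + h * h / 4.0),
                                       rel=1e-12)

    def test_pyramid_matches_standard_result(self):
        a, b, h = 0.08, 0.05, 0.25
        s = GeometricSolid(
            "rectangular_pyramid", {"base_a": a, "base_b": b, "length": h},
            density=900.0,
        )
        mass, com, t = solid_inertia(s)
        assert com[2] == pytest.approx(h / 4.0)
        assert t.i_xx == pytest.approx(mass * (b * b / 20.0 + 3 * h * h / 80.0),
                                       rel=1e-12)
        assert t.i_zz == pytest.approx(mass * (a * a + b * b) / 20.0, rel=1e-12)

    @pytest.mark.parametrize("shape", SHAPES)
    def test_invalid_dimensions_rejected(self, shape):
        dims = {
            "cylinder": {"radius": -0.1, "length": 0.2},
            "cone": {"radius": 0.1, "length": 0.0},
            "conical_frustum": {"r_proximal": 0.1, "r_distal": -0.05, "length": 0.2},
            "rectangular_pyramid": {"base_a": 0.1, "base_b": 0.1, "length": -1},
            "ellipsoid": {"semi_a": 0.0, "semi_b": 0.1, "semi_c": 0.1},
        }[shape]
        with pytest.raises(InvalidGeometryError):
            GeometricSolid(shape, dims, density=1000.0)

    def test_mass_xor_density_required(self):
        with pytest.raises(InvalidGeometryError):
            GeometricSolid("cylinder", {"radius": 0.1, "length": 0.2})
        with pytest.raises(InvalidGeometryError):
            GeometricSolid("cylinder", {"radius": 0.1, "length": 0.2},
                           density=1.0, mass=1.0)


class TestVoxelOracle:
    def test_box_closed_form(self):
        # unit-density unit cube: I_xx = m/6 about the CoM
        t = cuboid_inertia(1.0, 1.0, 1.0, 1.0)
        assert np.allclose(t.diagonal(), 1.0 / 6.0)

    def test_sphere_within_one_percent(self):
        r = 0.1
        s = GeometricSolid("ellipsoid",
                           {"semi_a": r, "semi_b": r, "semi_c": r}, density=1000.0)
        mass_a, _, t_a = solid_inertia(s)
        mass_n, com_n, t_n = numeric_inertia(s, 200)
        assert mass_n == pytest.approx(mass_a, rel=0.005)
        assert np.allclose(t_n.diagonal(), 0.4 * mass_a * r * r, rtol=0.01)

    def test_cone_example_within_half_percent(self):
        s = GeometricSolid("cone", {"radius": 0.05, "length": 0.2}, density=1000.0)
        mass_a, com_a, t_a = solid_inertia(s)
        mass_n, com_n, t_n = numeric_inertia(s, 200)
        assert mass_n == pytest.approx(mass_a, rel=0.005)
        assert np.allclose(com_n, com_a, atol=0.0005)
        assert np.allclose(t_n.diagonal(), t_a.diagonal(), rtol=0.005)

    @pytest.mark.parametrize("shape", SHAPES)
    def test_random_solids_agree_with_closed_form(self, shape, rng):
        for _ in range(5):
            s = random_solid(shape, rng)
            mass_a, com_a, t_a = solid_inertia(s)
            mass_n, com_n, t_n = numeric_inertia(s, 150)
            assert mass_n == pytest.approx(mass_a, rel=0.005)
            assert np.allclose(t_n.diagonal(), t_a.diagonal(), rtol=0.015)
            # symmetry frame: products vanish
            assert np.allclose(t_n.products(), 0.0,
                               atol=0.01 * t_a.diagonal().max())

    def test_resolution_floor(self):
        s = GeometricSolid("cylinder", {"radius": 0.1, "length": 0.2}, mass=1.0)
        with pytest.raises(ValueError):
            numeric_inertia(s, 49)

    @pytest.mark.parametrize("shape", SHAPES)
    def test_triangle_inequality_on_generated_tensors(self, shape, rng):
        for _ in range(10):
            s = random_solid(shape, rng)
            _, _, t = solid_inertia(s)
            assert t.triangle_violations() == []
            assert np.all(t.diagonal() >= 0)


class TestParallelAxis:
    def test_zero_shift_is_identity(self, rng):
        t = random_tensor(rng)
        shifted = parallel_axis(t, 2.0, np.zeros(3), frame_point="com")
        assert np.allclose(shifted.matrix(), t.matrix())

    def test_point_mass(self):
        zero = InertiaTensor(0.0, 0.0, 0.0)
        m, l = 3.0, 0.4
        t = parallel_axis(zero, m, [l, 0.0, 0.0])
        assert t.i_yy == pytest.approx(m * l * l)
        assert t.i_zz == pytest.approx(m * l * l)
        assert t.i_xx == 0.0

    def test_shift_unshift_round_trip(self, rng):
        for _ in range(20):
            t = random_tensor(rng)
            m = rng.uniform(0.5, 5.0)
            d = rng.normal(size=3)
            back = parallel_axis(parallel_axis(t, m, d), -m, d)
            assert np.allclose(back.matrix(), t.matrix(), atol=1e-14)


class TestMoiAboutAxis:
    def test_principal_axis_returns_diagonal(self):
        t = InertiaTensor(1.0, 2.0, 3.0)
        assert moi_about_axis(t, [1, 0, 0]) == pytest.approx(1.0)
        assert moi_about_axis(t, [0, 0, 1]) == pytest.approx(3.0)

    def test_diagonal_tensor_at_45_degrees(self):
        t = InertiaTensor(1.0, 2.0, 3.0)
        u = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
        assert moi_about_axis(t, u) == pytest.approx(1.5)

    def test_product_contribution_at_45_degrees(self):
        t = InertiaTensor(2.0, 3.0, 1.0, p_xy=0.5)
        u = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
        # 0.5*(2+3) - 2*0.5*0.5 = 2.0
        assert moi_about_axis(t, u) == pytest.approx(2.0)

    def test_non_unit_axis_error_and_warn_modes(self):
        t = InertiaTensor(1.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            moi_about_axis(t, [1.0, 1.0, 0.0])
        with pytest.warns(UserWarning):
            val = moi_about_axis(t, [2.0, 0.0, 0.0], on_non_unit="warn")
        assert val == pytest.approx(1.0)

    def test_trace_invariance_over_orthonormal_triads(self, rng):
        t = random_tensor(rng)
        trace = t.i_xx + t.i_yy + t.i_zz
        for _ in range(10):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            total = sum(moi_about_axis(t, q[:, j]) for j in range(3))
            assert total == pytest.approx(trace, rel=1e-10)
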