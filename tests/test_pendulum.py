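"""Period estimation, compound-pendulum inversion and product recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caninebsp.inertial_math import (
    GeometricSolid,
    InertiaTensor,
    cuboid_inertia,
    moi_about_axis,
    solid_inertia,
)
from caninebsp.pendulum import (
    BoxCalibration,
    InsufficientCyclesError,
    MeasurementWarning,
    OscillationTrace,
    PendulumTrial,
    SkewAxisMeasurement,
    average_masses,
    com_from_balance,
    estimate_period,
    pivot_moi,
    product_moi,
    segment_com_moi,
    skew_axis_vector,
)
from conftest import random_tensor

G = 9.81


def cosine_trace(period, n_cycles=10, rate=100.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(int(n_cycles * period * rate)) / rate
    x = np.cos(2 * np.pi * t / period)
    if noise:
        x = x + rng.normal(0, noise, size=t.size)
    return OscillationTrace(rate, x)


class TestEstimatePeriod:
    def test_noiseless_cosine(self):
        assert estimate_period(cosine_trace(1.8)) == pytest.approx(1.8, abs=0.01)

    def test_noisy_cosine_within_one_percent(self):
        t = estimate_period(cosine_trace(1.8, noise=0.05, seed=42))
        assert t == pytest.approx(1.8, rel=0.01)

    def test_constant_signal_rejected(self):
        with pytest.raises(InsufficientCyclesError):
            estimate_period(OscillationTrace(100.0, np.ones(500)))

    def test_too_few_cycles_rejected(self):
        with pytest.raises(InsufficientCyclesError):
            estimate_period(cosine_trace(1.8, n_cycles=2))

    def test_unrefined_estimate_still_close(self):
        t = estimate_period(cosine_trace(1.2, noise=0.05, seed=7), refine=False)
        assert t == pytest.approx(1.2, rel=0.01)


class TestPivotMoi:
    def test_point_mass_period(self):
        # T = 2*pi/sqrt(g) is the 1 m point-mass pendulum: I_pivot = m l^2 = 1
        assert pivot_moi(1.0, 1.0, 2 * np.pi / np.sqrt(G), G) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        assert pivot_moi(2.0, 0.5, 1.5, 9.81) == pytest.approx(
            2.0 * 9.81 * 0.5 * 2.25 / (4 * np.pi**2)
        )
        assert pivot_moi(2.0, 0.5, 1.5, 9.81) == pytest.approx(0.5591, abs=2e-4)

    def test_period_squared_scaling(self):
        assert pivot_moi(1.0, 1.0, 2.0) == pytest.approx(4 * pivot_moi(1.0, 1.0, 1.0))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            pivot_moi(0.0, 1.0, 1.0)


class TestSegmentComMoi:
    def test_point_segment_at_pivot_distance(self):
        T = 2 * np.pi / np.sqrt(G)
        box = PendulumTrial(1.0, 1.0, T, "empty_box")
        # composite twice the mass, same period: extra point mass at l=1
        comp = PendulumTrial(2.0, 1.0, T, "composite")
        assert segment_com_moi(comp, box, 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_composite_equals_box_gives_zero(self):
        tr = PendulumTrial(1.3, 0.8, 1.1, "empty_box")
        comp = PendulumTrial(1.3, 0.8, 1.1, "composite")
        assert segment_com_moi(comp, tr, 0.0, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_forward_simulated_cylinder_recovered(self):
        cyl = GeometricSolid("cylinder", {"radius": 0.04, "length": 0.3}, mass=1.5)
        m_s, _, tensor = solid_inertia(cyl)
        box_mass, l = 0.2, 0.35
        box_tensor = cuboid_inertia(box_mass, 0.1, 0.1, 0.36)
        for axis, true in (("x", tensor.i_xx), ("z", tensor.i_zz)):
            u = {"x": [1, 0, 0], "z": [0, 0, 1]}[axis]
            i_c = true + moi_about_axis(box_tensor, u) + (m_s + box_mass) * l * l
            i_b = moi_about_axis(box_tensor, u) + box_mass * l * l
            t_c = 2 * np.pi * np.sqrt(i_c / ((m_s + box_mass) * G * l))
            t_b = 2 * np.pi * np.sqrt(i_b / (box_mass * G * l))
            got = segment_com_moi(
                PendulumTrial(m_s + box_mass, l, t_c),
                PendulumTrial(box_mass, l, t_b, "empty_box"),
                m_s, l,
            )
            assert got == pytest.approx(true, rel=0.005)

    def test_negative_result_warned_not_clamped(self):
        box = PendulumTrial(1.0, 1.0, 2.0, "empty_box")
        comp = PendulumTrial(1.5, 1.0, 2.0, "composite")
        with pytest.warns(MeasurementWarning):
            val = segment_com_moi(comp, box, 0.5, 1.0)
        assert val < 0.0


class TestProductMoi:
    def test_known_skew_axis_case(self):
        t = InertiaTensor(2.0, 3.0, 1.0, p_xy=0.5)
        theta = np.pi / 4
        i_star = moi_about_axis(t, skew_axis_vector("xy", theta))
        assert i_star == pytest.approx(2.0)
        meas = SkewAxisMeasurement(t.i_xx, t.i_yy, i_star, theta)
        assert product_moi(meas) == pytest.approx(0.5)

    def test_symmetric_tensor_gives_zero(self):
        meas = SkewAxisMeasurement(2.0, 3.0, 2.5, np.pi / 4)
        assert product_moi(meas) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        theta=st.floats(np.deg2rad(10), np.deg2rad(80)),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_exact_inverse_of_quadratic_form(self, theta, seed):
        t = random_tensor(np.random.default_rng(seed))
        for pair, (a, b) in (("xy", ("i_xx", "i_yy")),
                             ("xz", ("i_xx", "i_zz")),
                             ("yz", ("i_yy", "i_zz"))):
            i_star = moi_about_axis(t, skew_axis_vector(pair, theta))
            meas = SkewAxisMeasurement(getattr(t, a), getattr(t, b), i_star, theta)
            true = getattr(t, "p_" + pair)
            assert product_moi(meas) == pytest.approx(true, rel=1e-9, abs=1e-12)

    def test_ill_conditioned_angles_rejected(self):
        with pytest.raises(ValueError):
            SkewAxisMeasurement(1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            product_moi(SkewAxisMeasurement(1.0, 1.0, 1.0, np.pi / 2 - 1e-9))


class TestComFromBalance:
    def test_moment_balance_example(self):
        box = BoxCalibration(1.0, [0.5, 0.5, 0.5], InertiaTensor(0.1, 0.1, 0.1))
        com = com_from_balance([0.4, 0.5, 0.5], box, 2.0)
        assert com[0] == pytest.approx(0.35)

    def test_coincident_coms(self):
        box = BoxCalibration(1.0, [0.3, 0.2, 0.1], InertiaTensor(0.1, 0.1, 0.1))
        com = com_from_balance([0.3, 0.2, 0.1], box, 4.0)
        assert np.allclose(com, [0.3, 0.2, 0.1])

    def test_heavy_segment_limit(self):
        box = BoxCalibration(1e-6, [0.9, 0.9, 0.9], InertiaTensor(1e-9, 1e-9, 1e-9))
        com = com_from_balance([0.2, 0.3, 0.4], box, 50.0)
        assert np.allclose(com, [0.2, 0.3, 0.4], atol=1e-6)

    def test_nonpositive_mass_rejected(self):
        box = BoxCalibration(1.0, [0, 0, 0], InertiaTensor(0.1, 0.1, 0.1))
        with pytest.raises(ValueError):
            com_from_balance([0, 0, 0], box, 0.0)


class TestAverageMasses:
    def test_identical_masses(self):
        mean, spread = average_masses(1.0, 1.0, 1.0)
        assert (mean, spread) == (1.0, 0.0)

    def test_small_spread(self):
        mean, spread = average_masses(0.99, 1.00, 1.01)
        assert mean == pytest.approx(1.0)
        assert spread == pytest.approx(0.02)

    def test_large_spread_warns(self):
        with pytest.warns(MeasurementWarning):
            mean, spread = average_masses(1.0, 1.0, 0.5)
        assert mean == pytest.approx(0.8333, abs=1e-4)
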