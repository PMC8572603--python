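"""Path-geometry tests: rotation, lengths, moment arms, velocity.

The moment-arm formula is cross-checked against the cross-product
point-line distance, and against the musculotendon-length derivative
(virtual-work identity); derived length values were frozen from hand
evaluation of the published coordinates.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elbownms import (
    JointTrajectory,
    extensor_moment_arm,
    extensor_mt_length,
    fiber_length,
    fiber_velocity,
    flexor_moment_arm,
    flexor_mt_length,
    rotate_insertion,
)
from elbownms.geometry import (
    DegenerateGeometryError,
    InfeasiblePostureError,
    rotation_matrix,
)

BICEPS_ORIGIN = (0.023, 0.0, 0.115)
BICEPS_INSERTION = (0.007, 0.0, -0.047)


def cross_product_distance(origin, insertion):
    """Independent point-line distance |A x C| / |A - C| in the xz plane."""
    xa, _, za = origin
    xc, _, zc = insertion
    num = abs(xa * zc - xc * za)
    den = math.hypot(xa - xc, za - zc)
    return num / den


class TestRotation:
    def test_identity_at_zero(self):
        p = np.array(BICEPS_INSERTION)
        assert np.allclose(rotate_insertion(p, 0.0), p)
        assert np.allclose(rotation_matrix(0.0), np.eye(3))

    def test_ninety_degrees_hand_value(self):
        out = rotate_insertion(BICEPS_INSERTION, 90.0)
        assert out == pytest.approx([0.047, 0.0, 0.007], abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        theta=st.floats(-180, 180),
        x=st.floats(-0.2, 0.2),
        z=st.floats(-0.2, 0.2),
    )
    def test_norm_preserved(self, theta, x, z):
        p = np.array([x, 0.0, z])
        out = rotate_insertion(p, theta)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(p), abs=1e-12)


class TestFlexorLength:
    def test_biceps_extension_hand_value(self):
        # sqrt(0.016^2 + 0.162^2) + 0.263, hand-evaluated
        l_mt = flexor_mt_length(BICEPS_ORIGIN, BICEPS_INSERTION, 0.263)
        assert l_mt == pytest.approx(0.42578820596099706, abs=1e-12)

    def test_collinear_simple_case(self):
        assert flexor_mt_length((0.5, 0, 0), (0.2, 0, 0), 0.0) == pytest.approx(0.3)

    def test_coincident_points_error(self):
        with pytest.raises(DegenerateGeometryError):
            flexor_mt_length((0.1, 0, 0.2), (0.1, 0, 0.2))

    def test_biceps_shortens_with_flexion(self):
        thetas = np.linspace(0, 90, 91)
        lengths = [
            flexor_mt_length(
                BICEPS_ORIGIN, rotate_insertion(BICEPS_INSERTION, th), 0.263
            )
            for th in thetas
        ]
        assert np.all(np.diff(lengths) < 0)


class TestFiberLength:
    def test_biceps_hand_value(self):
        l_m, l_t = fiber_length(0.42578820596099706, 0.272, 1.02)
        assert l_t == pytest.approx(0.27744, abs=1e-12)
        assert l_m == pytest.approx(0.14834820596099704, abs=1e-12)

    def test_zero_tendon_passthrough(self):
        l_m, l_t = fiber_length(0.3, 0.0, 1.0)
        assert (l_m, l_t) == (0.3, 0.0)

    def test_infeasible_posture_names_muscle(self):
        with pytest.raises(InfeasiblePostureError, match="biceps_long.*theta=42"):
            fiber_length(0.27744, 0.272, 1.02, name="biceps_long", theta_deg=42)


class TestFlexorMomentArm:
    def test_vertical_line(self):
        assert flexor_moment_arm((1.0, 0, 0.0), (1.0, 0, 1.0)) == pytest.approx(1.0)

    def test_horizontal_line(self):
        assert flexor_moment_arm((0.0, 0, 1.0), (1.0, 0, 1.0)) == pytest.approx(1.0)

    def test_cross_product_oracle_over_flexion(self):
        for th in np.linspace(0, 120, 121):
            ins = rotate_insertion(BICEPS_INSERTION, th)
            r = flexor_moment_arm(BICEPS_ORIGIN, ins)
            assert r == pytest.approx(
                cross_product_distance(BICEPS_ORIGIN, ins), abs=1e-12
            )

    @pytest.mark.parametrize(
        "origin,insertion,l_0",
        [
            (BICEPS_ORIGIN, BICEPS_INSERTION, 0.263),
            ((0.023, 0.0, 0.115), (0.007, 0.0, -0.047), 0.178),
            ((0.008, 0.0, 0.115), (0.007, 0.0, -0.023), 0.010),
        ],
        ids=["biceps_long", "biceps_short", "brachialis"],
    )
    def test_virtual_work_identity(self, origin, insertion, l_0):
        # |d l_mt / d theta_rad| equals the moment arm for a point
        # rotating about the joint centre
        h = 1e-4  # degrees
        for th in np.linspace(0.5, 120, 60):
            lp = flexor_mt_length(origin, rotate_insertion(insertion, th + h), l_0)
            lm = flexor_mt_length(origin, rotate_insertion(insertion, th - h), l_0)
            dl_dtheta_rad = (lp - lm) / (2 * h * math.pi / 180)
            r = flexor_moment_arm(origin, rotate_insertion(insertion, th))
            assert abs(abs(dl_dtheta_rad) - r) < 1e-6


class TestExtensorPath:
    def test_arm_at_extension_and_ninety(self):
        assert extensor_moment_arm(0.0, 0.022, 0.004) == pytest.approx(0.022)
        assert extensor_moment_arm(90.0, 0.022, 0.004) == pytest.approx(0.018)

    def test_arm_linearity(self):
        r0, r45, r90 = (
            extensor_moment_arm(th, 0.022, 0.004) for th in (0.0, 45.0, 90.0)
        )
        assert r45 == pytest.approx((r0 + r90) / 2, abs=1e-15)

    def test_arm_must_stay_positive(self):
        with pytest.raises(ValueError):
            extensor_moment_arm(90.0, 0.003, 0.004)

    def test_arc_length_hand_value(self):
        # 0.134 + (pi/2) * 0.02
        assert extensor_mt_length(90.0, 0.02, 0.134) == pytest.approx(
            0.16541592653589794, abs=1e-12
        )
        assert extensor_mt_length(0.0, 0.02, 0.134) == pytest.approx(0.134)

    def test_literal_mode_drops_pi(self):
        assert extensor_mt_length(90.0, 0.02, 0.134, literal=True) == pytest.approx(
            0.134 + 90 * 0.02 / 180
        )

    def test_arc_derivative_is_moment_arm(self):
        r = 0.02
        h = 1e-5
        d = (
            extensor_mt_length(30 + h, r, 0.134) - extensor_mt_length(30 - h, r, 0.134)
        ) / (2 * h * math.pi / 180)
        assert d == pytest.approx(r, abs=1e-9)


class TestFiberVelocity:
    def test_constant_length_zero_velocity(self):
        t = np.linspace(0, 2, 201)
        v = fiber_velocity(np.full_like(t, 0.1), t, 0.1, 8.0)
        assert np.allclose(v, 0.0)

    def test_linear_ramp(self):
        t = np.linspace(0, 2, 201)
        l_mopt = 0.1
        l_m = l_mopt * (1 + 0.1 * t)
        v = fiber_velocity(l_m, t, l_mopt, 8.0)
        assert np.allclose(v, 0.1 / 8.0, atol=1e-12)

    def test_sinusoid_matches_analytic_derivative(self):
        dt = 0.005
        t = np.arange(0, 2 + dt / 2, dt)
        l_mopt, amp, w = 0.1, 0.01, 2 * math.pi
        l_m = l_mopt + amp * np.sin(w * t)
        v = fiber_velocity(l_m, t, l_mopt, 8.0)
        analytic = amp * w * np.cos(w * t) / (8.0 * l_mopt)
        # central differences: O(dt^2) interior, O(dt) at the ends
        assert np.max(np.abs(v[1:-1] - analytic[1:-1])) < 5 * dt**2 * w**2
        assert np.max(np.abs(v - analytic)) < 2 * dt * w

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fiber_velocity([0.1, 0.1], [0.0, 0.1], 0.1, 8.0)


class TestJointTrajectory:
    def test_rejects_nonuniform_time(self):
        with pytest.raises(ValueError):
            JointTrajectory(t=np.array([0, 0.1, 0.3]), theta=np.zeros(3))

    def test_rejects_out_of_range_angle(self):
        with pytest.raises(ValueError):
            JointTrajectory(t=np.array([0, 0.1]), theta=np.array([0.0, 160.0]))
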