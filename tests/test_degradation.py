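"""Gabor operator, alpha schedule and the diffusion forward/inverse algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pactdiff.degradation import (
    DegradationOperator,
    DiffusionSchedule,
    GaborParams,
    alpha_schedule,
    build_operator,
    estimate_endpoint,
    forward_degrade,
    gabor_value,
    renoise_step,
)


class TestGaborValue:
    def test_center_is_one_at_zero_phase(self):
        assert gabor_value(GaborParams(psi=0.0), 0, 0) == pytest.approx(1.0)

    def test_center_is_zero_at_quarter_phase(self):
        assert gabor_value(GaborParams(psi=np.pi / 2), 0, 0) == pytest.approx(0.0)

    def test_axis_aligned_point_value(self):
        # theta=0, lam=4, sigma=10: i'=2 -> exp(-4/200) * cos(pi) = -exp(-0.02)
        p = GaborParams(theta=0.0, lam=4.0, sigma=10.0, psi=0.0, gamma=1.0)
        assert gabor_value(p, 2, 0) == pytest.approx(-np.exp(-0.02), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            GaborParams(lam=-1.0)
        with pytest.raises(ValueError):
            GaborParams(sigma=0.0)


class TestBuildOperator:
    def test_mask_shape_and_envelope_bound(self):
        op = build_operator(GaborParams(), (64, 48))
        assert op.mask.shape == (64, 48)
        assert np.abs(op.mask).max() <= 1.0

    @pytest.mark.parametrize("mode", ["frequency_mask", "spatial_mask"])
    def test_linearity(self, mode, rng):
        op = build_operator(GaborParams(), (16, 16), mode)
        x = rng.standard_normal((16, 16))
        y = rng.standard_normal((16, 16))
        lhs = op.apply(2.5 * x - 1.5 * y)
        rhs = 2.5 * op.apply(x) - 1.5 * op.apply(y)
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_invalid_mode_and_shape(self):
        with pytest.raises(ValueError):
            build_operator(GaborParams(), (16, 16), "conv")
        with pytest.raises(ValueError):
            build_operator(GaborParams(), (1, 16))


class TestAlphaSchedule:
    def test_two_step_endpoints(self):
        sched = alpha_schedule(2)
        assert np.allclose(sched.alphas, [0.999, 0.0])

    def test_three_step_midpoint(self):
        sched = alpha_schedule(3)
        assert np.allclose(sched.alphas, [0.999, 0.4995, 0.0])

    @pytest.mark.parametrize("T", [2, 3, 5, 17])
    def test_strictly_decreasing(self, T):
        a = alpha_schedule(T).alphas
        assert np.all(np.diff(a) < 0)
        assert a[0] == pytest.approx(0.999) and a[-1] == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            alpha_schedule(1)


class TestForwardDegrade:
    def test_endpoint_returns_xT_bit_exact(self, rng):
        op = build_operator(GaborParams(), (16, 16))
        sched = alpha_schedule(2)
        x0 = rng.random((16, 16))
        xT = rng.random((16, 16))
        assert np.array_equal(forward_degrade(x0, xT, 2, op, sched), xT)

    def test_fixed_point_when_endpoint_equals_clean(self, rng):
        op = build_operator(GaborParams(), (16, 16))
        sched = alpha_schedule(4)
        x = rng.random((16, 16))
        for t in range(1, 5):
            assert np.allclose(forward_degrade(x, x, t, op, sched), x, atol=1e-12)

    def test_uniform_mask_half_alpha(self):
        # all-ones spatial mask and alpha = 0.5 interpolate exactly halfway
        op = DegradationOperator(mask=np.ones((4, 4)), domain_mode="spatial_mask")
        sched = DiffusionSchedule(T=2, alphas=np.array([0.5, 0.0]))
        xt = forward_degrade(np.ones((4, 4)), np.zeros((4, 4)), 1, op, sched)
        assert np.allclose(xt, 0.5)

    def test_shape_mismatch_rejected(self):
        op = build_operator(GaborParams(), (8, 8))
        with pytest.raises(ValueError):
            forward_degrade(np.zeros((8, 8)), np.zeros((4, 4)), 1, op, alpha_schedule(2))


class TestEndpointEstimate:
    @pytest.mark.parametrize("mode", ["frequency_mask", "spatial_mask"])
    def test_roundtrip_inverts_forward(self, mode, rng):
        op = build_operator(GaborParams(), (24, 24), mode)
        sched = alpha_schedule(4)
        x0 = rng.random((24, 24))
        xT = rng.random((24, 24))
        for t in range(1, 4):  # t < T so alpha > 0
            xt = forward_degrade(x0, xT, t, op, sched)
            back = estimate_endpoint(xt, x0, t, op, sched)
            assert np.max(np.abs(back - xT)) < 1e-6 * max(1.0, np.abs(xT).max())

    def test_final_step_returns_input_unchanged(self, rng):
        op = build_operator(GaborParams(), (8, 8))
        sched = alpha_schedule(2)
        xt = rng.random((8, 8))
        assert np.array_equal(estimate_endpoint(xt, rng.random((8, 8)), 2, op, sched), xt)

    def test_guard_keeps_output_finite_at_unit_transfer(self):
        op = DegradationOperator(mask=np.ones((6, 6)), domain_mode="spatial_mask")
        sched = DiffusionSchedule(T=2, alphas=np.array([1.0, 0.0]))
        out = estimate_endpoint(np.full((6, 6), 3.0), np.ones((6, 6)), 1, op, sched)
        assert np.all(np.isfinite(out))


class TestRenoiseStep:
    def test_reproduces_true_intermediate_with_oracle_inputs(self, rng):
        op = build_operator(GaborParams(), (16, 16))
        sched = alpha_schedule(3)
        x0 = rng.random((16, 16))
        xT = rng.random((16, 16))
        for t in (2, 3):
            xt = forward_degrade(x0, xT, t, op, sched)
            out = renoise_step(xt, x0, xT, t, op, sched)
            expected = forward_degrade(x0, xT, t - 1, op, sched)
            assert np.max(np.abs(out - expected)) < 1e-6

    def test_degenerate_equal_estimates_return_xt(self, rng):
        op = build_operator(GaborParams(), (8, 8))
        sched = alpha_schedule(3)
        xt = rng.random((8, 8))
        z = rng.random((8, 8))
        assert np.allclose(renoise_step(xt, z, z, 2, op, sched), xt, atol=1e-12)

    def test_rejects_first_step(self):
        op = build_operator(GaborParams(), (8, 8))
        with pytest.raises(ValueError):
            renoise_step(np.zeros((8, 8)), np.zeros((8, 8)), np.zeros((8, 8)), 1,
                         op, alpha_schedule(2))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    t=st.integers(1, 3),
    mode=st.sampled_from(["frequency_mask", "spatial_mask"]),
    theta=st.floats(0, np.pi, allow_nan=False),
    lam=st.floats(1.5, 10.0, allow_nan=False),
)
def test_forward_inverse_roundtrip_property(seed, t, mode, theta, lam):
    """estimate_endpoint inverts forward_degrade for any operator and t < T."""
    rng = np.random.default_rng(seed)
    op = build_operator(GaborParams(theta=theta, lam=lam), (12, 12), mode)
    sched = alpha_schedule(4)
    x0 = rng.random((12, 12))
    xT = rng.random((12, 12))
    xt = forward_degrade(x0, xT, t, op, sched)
    back = estimate_endpoint(xt, x0, t, op, sched)
    assert np.max(np.abs(back - xT)) < 1e-6
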