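"""Device-law unit tests: current equation, state dynamics, analytic ops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memhh as M
from memhh.device import SINH_ARG_LIMIT


class TestDeviceCurrent:
    def test_pinched_at_origin(self, nbox):
        for w in (nbox.w_min, 0.5, nbox.w_max):
            assert M.device_current(nbox, w, 0.0) == 0.0

    def test_known_value_at_read_voltage(self, nbox):
        # independent arithmetic of the two conduction terms at w=0.117, V=0.7
        expected = (1 - 0.117) * 0.0271 * (1 - np.exp(-0.503 * 0.7)) \
            + 0.117 * 11.138 * np.sinh(0.739 * 0.7)
        assert M.device_current(nbox, 0.117, 0.7) == pytest.approx(expected, rel=1e-12)
        assert M.device_current(nbox, 0.117, 0.7) == pytest.approx(0.712, abs=5e-4)

    @given(w=st.floats(0.117, 0.99), V=st.floats(-5.0, 5.0))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_sign_follows_voltage(self, nbox, w, V):
        i = M.device_current(nbox, w, V)
        if V == 0:
            assert i == 0.0
        else:
            assert np.sign(i) == np.sign(V)

    def test_odd_sign_structure(self, nbox):
        i_pos = M.device_current(nbox, nbox.w_min, 0.8)
        i_neg = M.device_current(nbox, nbox.w_min, -0.8)
        assert i_pos > 0 > i_neg

    def test_out_of_bounds_state_rejected(self, nbox):
        with pytest.raises(ValueError):
            M.device_current(nbox, 1.5, 0.5)


class TestWindow:
    def test_zero_at_three(self, nbox):
        assert M.window(nbox, 3.0) == pytest.approx(0.0, abs=1e-15)

    def test_reference_values(self, nbox):
        assert M.window(nbox, 0.117) == pytest.approx(1 - np.exp(0.117 - 3), rel=1e-14)
        assert M.window(nbox, 0.117) == pytest.approx(0.944, abs=5e-4)
        assert M.window(nbox, 0.99) == pytest.approx(0.866, abs=5e-4)

    def test_strictly_decreasing(self, nbox):
        w = np.linspace(0.0, 1.0, 50)
        assert np.all(np.diff(M.window(nbox, w)) < 0)


class TestStateDynamics:
    def test_rate_zero_at_baseline_unbiased(self, nbox, wox):
        for p in (nbox, wox):
            assert M.state_rate(p, p.w_min, 0.0) == 0.0

    def test_rate_positive_under_bias(self, nbox):
        assert M.state_rate(nbox, nbox.w_min, 0.5) > 0

    def test_pure_decay_value(self, nbox):
        # decay term alone: -(0.3 - 0.117) / 11.7
        assert M.state_rate(nbox, 0.3, 0.0) == pytest.approx(-(0.3 - 0.117) / 11.7, rel=1e-12)

    def test_step_fixed_point_and_clip(self, nbox):
        assert M.step_state(nbox, nbox.w_min, 0.0, 0.01) == nbox.w_min
        assert M.step_state(nbox, 0.98, 30.0, 1.0) == nbox.w_max

    def test_step_matches_hand_euler(self, nbox):
        w, V, dt = 0.117, 4.0, 0.005
        expected = w + dt * (M.window(nbox, w) * nbox.lam * np.sinh(nbox.eta * V)
                             - (w - nbox.w_min) / nbox.tau)
        assert M.step_state(nbox, w, V, dt) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_dt_rejected(self, nbox):
        with pytest.raises(ValueError):
            M.step_state(nbox, 0.5, 1.0, 0.0)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_state_confined_under_arbitrary_stimulus(self, nbox, seed):
        rng = np.random.default_rng(seed)
        V = rng.uniform(-6, 6, size=2000)
        tr = M.simulate_device(nbox, V, dt=0.01)
        assert np.all(tr["w"] >= nbox.w_min)
        assert np.all(tr["w"] <= nbox.w_max)


class TestSteadyState:
    def test_baseline_at_zero_bias(self, nbox):
        assert M.steady_state_w(nbox, 0.0) == nbox.w_min

    def test_reference_value(self, nbox):
        # w_min + tau*lam*sinh(eta*1V)
        assert M.steady_state_w(nbox, 1.0) == pytest.approx(0.2636, abs=5e-4)

    def test_saturation_voltage(self, nbox):
        v_sat = np.arcsinh(nbox.w_max / (nbox.tau * nbox.lam)) / nbox.eta
        assert M.steady_state_w(nbox, v_sat * 1.001) == pytest.approx(nbox.w_max)

    def test_monotone_in_voltage(self, nbox, wox):
        for p in (nbox, wox):
            V = np.linspace(0, 8, 100)
            w = M.steady_state_w(p, V)
            assert np.all(np.diff(w) >= -1e-15)


class TestEffectiveTimeConstant:
    def test_weak_drive_is_tau(self, nbox):
        assert M.effective_time_constant(nbox, 0.0) == nbox.tau

    def test_strong_drive_formula(self, nbox):
        # pick V such that tau*lam*sinh(eta V) = 10 -> constant is tau/10
        V = np.arcsinh(10.0 / (nbox.tau * nbox.lam)) / nbox.eta
        assert M.effective_time_constant(nbox, V) == pytest.approx(nbox.tau / 10, rel=1e-9)

    def test_branch_predicate_per_device(self, nbox, wox):
        for p in (nbox, wox):
            for V in (0.3, 1.0, 3.0):
                drive = p.tau * p.lam * np.sinh(p.eta * V)
                expect = p.tau if drive < 1 else 1 / (p.lam * np.sinh(p.eta * V))
                assert M.effective_time_constant(p, V) == pytest.approx(expect)
                assert M.effective_time_constant(p, V) <= p.tau * (1 + 1e-12)


class TestLinearization:
    def test_zero_at_origin(self, nbox):
        assert M.linearized_current(nbox, 0.5, 0.0) == 0.0

    def test_explicit_coefficients(self, nbox):
        w, V = 0.5, 0.01
        expected = (w * (11.138 * 0.739 - 0.0271 * 0.503) + 0.0271 * 0.503) * V
        assert M.linearized_current(nbox, w, V) == pytest.approx(expected, rel=1e-12)

    def test_residual_is_second_order(self, nbox):
        # |i - i_lin| <= C V^2 on |V| <= 0.05; the normalized residual must
        # stay bounded (and shrink) as V -> 0, i.e. the error is o(V)
        w = 0.4
        V = np.array([0.05, 0.025, 0.0125, 0.00625])
        resid = np.abs(M.device_current(nbox, w, V) - M.linearized_current(nbox, w, V))
        ratio = resid / V**2
        assert np.all(ratio < 0.05)          # C bound, fixed numerically
        assert np.all(np.diff(ratio) < 0)    # dominated by higher-order terms
        assert resid[-1] / V[-1] < 1e-3      # residual / |V| -> 0

    def test_linear_variant_conductance_independent_of_voltage(self, nbox):
        w = 0.3
        g = [M.linear_variant_current(nbox, w, V) / V for V in (0.01, 0.5, 3.0)]
        assert g[0] == pytest.approx(g[1], rel=1e-12) == pytest.approx(g[2], rel=1e-12)


class TestHysteresisAndIntegration:
    def test_zero_amplitude_gives_zero_current(self, nbox):
        tr = M.hysteresis_trace(nbox, amplitude=0.0, freq=0.05, dt=0.01, cycles=2)
        assert np.allclose(tr["i"], 0.0)

    def test_pinched_at_every_voltage_zero(self, nbox):
        tr = M.hysteresis_trace(nbox, amplitude=2.0, freq=0.02, dt=0.005, cycles=2)
        zero_v = np.abs(tr["V"]) < 1e-12
        assert zero_v.sum() >= 2
        assert np.all(np.abs(tr["i"][zero_v]) < 1e-12)

    def test_loop_area_positive_near_tau_period(self, nbox):
        # drive period comparable to tau -> state lags -> open loop
        freq = 1.0 / nbox.tau
        tr = M.hysteresis_trace(nbox, amplitude=2.0, freq=freq, dt=0.002, cycles=3)
        n = int(1 / (freq * 0.002))
        V, i = tr["V"][-n:], tr["i"][-n:]
        area = abs(np.trapezoid(i, V))
        assert area > 1e-3

    def test_forward_euler_dt_convergence(self, nbox):
        # halving dt moves the endpoint of a 100-ms trajectory by < 1%
        rng = np.random.default_rng(5)
        V_coarse = np.repeat(rng.uniform(0, 4, 100), 100)  # 100 ms at dt=0.01
        tr1 = M.simulate_device(nbox, V_coarse, dt=0.01)
        tr2 = M.simulate_device(nbox, np.repeat(V_coarse, 2), dt=0.005)
        assert tr2["w"][-1] == pytest.approx(tr1["w"][-1], rel=0.01)


def test_presets_round_trip(tmp_path, nbox):
    path = tmp_path / "dev.json"
    import json
    path.write_text(json.dumps(nbox.to_dict()))
    assert M.MemristorParams.from_json(path) == nbox
    with pytest.raises(KeyError):
        M.MemristorParams.preset("tiox")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        M.MemristorParams(tau=-1, alpha=0, beta=0, gamma=0, delta=0, eta=0,
                          lam=0, w_min=0.1)
    with pytest.raises(ValueError):
        M.MemristorParams(tau=1, alpha=0, beta=0, gamma=0, delta=0, eta=0,
                          lam=0, w_min=0.9, w_max=0.5)
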