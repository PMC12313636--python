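"""Calibration: reduced/full device fits, constraint penalties, scale search."""

import numpy as np
import pytest

import memhh as M
from memhh.calibration import (
    DEFAULT_CONSTRAINT_WEIGHTS,
    ReducedModelParams,
    _reduced_loss_and_grad,
    constraint_loss,
    fit_full,
    fit_reduced,
    fit_scaling,
    sensitivity_scan,
    simulate_reduced,
)
from memhh.synth import PulseProtocol, generate_potentiation_decay, generate_pulse_sweep

TRUTH = ReducedModelParams(tau=11.7, A=1.28, G_min=2.18)


class TestSimulateReduced:
    def test_constant_at_baseline_without_drive(self):
        tr = simulate_reduced(TRUTH, np.zeros(1000), dt=0.1)
        np.testing.assert_allclose(tr["G"], TRUTH.G_min)

    def test_exponential_decay_closed_form(self):
        tr = simulate_reduced(TRUTH, np.zeros(2000), dt=0.01, G0=TRUTH.G_min + 1.0)
        # forward-Euler decay tracks exp(-t/tau)
        expected = TRUTH.G_min + np.exp(-tr.t / TRUTH.tau)
        np.testing.assert_allclose(tr["G"], expected, atol=1e-3)

    def test_sawtooth_under_pulse_train(self):
        proto = PulseProtocol(noise_sd=0.0, replicates=1, n_pulses=4)
        V = M.pulse_voltage_waveform(proto)
        tr = simulate_reduced(TRUTH, V)
        on = V["V"] > 0
        dG = np.diff(tr["G"])
        assert np.all(dG[on[:-1]] > 0)       # charging during writes
        assert np.all(dG[~on[:-1]] <= 1e-12)  # relaxing in between


class TestReducedGradient:
    def test_bptt_gradient_matches_finite_differences(self):
        proto = PulseProtocol(noise_sd=0.0, replicates=1, n_pulses=3, dt=0.5)
        G, V = generate_potentiation_decay(TRUTH, proto)
        D = G["G"] + 0.3  # off-model data so the gradient is nonzero
        on = np.asarray(V["V"] > 0, dtype=float)
        theta = np.array([9.0, 1.0, 2.0])
        _, grad, _ = _reduced_loss_and_grad(theta, D, on, 0.5)
        for j in range(3):
            h = 1e-6 * theta[j]
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            lp, _, _ = _reduced_loss_and_grad(tp, D, on, 0.5)
            lm, _, _ = _reduced_loss_and_grad(tm, D, on, 0.5)
            assert grad[j] == pytest.approx((lp - lm) / (2 * h), rel=1e-5)


class TestFitReduced:
    def test_noiseless_recovery(self):
        proto = PulseProtocol(noise_sd=0.0, replicates=3)
        G, V = generate_potentiation_decay(TRUTH, proto, seed=0)
        res = fit_reduced(G, V, steps=6000)
        assert res.params["tau"] == pytest.approx(TRUTH.tau, rel=0.01)
        assert res.params["A"] == pytest.approx(TRUTH.A, rel=0.01)
        assert res.params["G_min"] == pytest.approx(TRUTH.G_min, rel=0.01)

    def test_degenerate_constant_data_does_not_diverge(self):
        n = 5000
        res = fit_reduced(np.full(n, TRUTH.G_min), np.zeros(n), dt=0.1, steps=500)
        assert np.isfinite(res.loss)
        assert res.params["A"] < 0.2          # potentiation rate driven to ~0
        assert res.params["G_min"] == pytest.approx(TRUTH.G_min, rel=0.05)

    def test_median_tau_recovery_under_measurement_noise(self):
        # parameter-recovery study at 1% multiplicative noise
        errs = []
        for seed in range(20):
            proto = PulseProtocol(noise_sd=0.01, replicates=2)
            G, V = generate_potentiation_decay(TRUTH, proto, seed=seed)
            res = fit_reduced(G, V, steps=2000, lr=2e-2)
            errs.append(abs(res.params["tau"] / TRUTH.tau - 1))
        assert np.median(errs) < 0.05
        assert max(errs) < 0.10


class TestConstraintLoss:
    def test_zero_iff_satisfied(self, nbox):
        params = dict(nbox.to_dict(), beta=0.5, w_min=0.15)
        total, terms = constraint_loss(params, w_trajectory=np.full(100, 0.9))
        assert total == 0.0

    def test_negative_parameter_penalty(self, nbox):
        params = dict(nbox.to_dict(), alpha=-0.1)
        total, terms = constraint_loss(params)
        assert terms["nonneg"] == pytest.approx(1e4 * 0.1)

    def test_table_values_give_small_anchor_penalties(self, nbox):
        total, terms = constraint_loss(nbox)
        assert terms["w_min_anchor"] == pytest.approx(1e3 * (0.117 - 0.15) ** 2)
        assert terms["beta_anchor"] == pytest.approx((0.503 - 0.5) ** 2)
        assert terms["overshoot"] == 0.0

    def test_overshoot_term(self, nbox):
        w_traj = np.array([0.5, 1.2, 1.1, 0.9])
        total, terms = constraint_loss(nbox, w_trajectory=w_traj)
        assert terms["overshoot"] == pytest.approx(1e2 * (1.2 + 1.1))

    def test_read_current_equality_optional(self, nbox):
        _, off = constraint_loss(nbox)
        assert off["read_current"] == 0.0
        _, on = constraint_loss(nbox, weights={"read_current": 1.0})
        i_read = M.device_current(nbox, nbox.w_min, 0.7)
        assert on["read_current"] == pytest.approx((i_read - 0.7 * 2.18) ** 2)


class TestFitFull:
    def test_zero_step_fit_returns_initialization(self, nbox):
        proto = PulseProtocol(noise_sd=0.0, n_pulses=2, replicates=1, dt=0.5)
        sweep = generate_pulse_sweep(nbox, [3.0], proto)
        init = {"alpha": 0.05, "beta": 0.5, "gamma": 5.0, "delta": 1.0,
                "eta": 1.0, "lam": 0.01, "w_min": 0.15}
        res = fit_full(sweep, tau=nbox.tau, steps=0, seed=0, init=init)
        for k, v in init.items():
            assert res.params[k] == pytest.approx(v, rel=1e-3)

    def test_loss_decomposition_is_additive(self, nbox):
        proto = PulseProtocol(noise_sd=0.0, n_pulses=2, replicates=1, dt=0.5)
        sweep = generate_pulse_sweep(nbox, [3.0], proto)
        res = fit_full(sweep, tau=nbox.tau, steps=0, seed=0)
        assert res.loss == pytest.approx(sum(res.loss_terms.values()), rel=1e-12)

    def test_constraints_needed_to_reject_unphysical_schottky_slope(self, nbox):
        # negative control: an implausible Schottky slope (beta ~ 10 1/V, with
        # alpha rescaled to compensate) fits the current data almost as well
        # as the truth, so the bare MSE cannot exclude it - only the printed
        # plausibility penalties can
        from memhh.calibration import _FULL_FIT_ORDER, _full_objective

        proto = PulseProtocol(noise_sd=0.0, n_pulses=3, replicates=1, dt=0.5)
        sweep_traces = generate_pulse_sweep(nbox, [2.0, 4.0], proto)
        sweep = [(np.ascontiguousarray(t["V"]), np.asarray(t["V_meas"]),
                  np.asarray(t["i"])) for t in sweep_traces]
        truth = {k: getattr(nbox, k) for k in _FULL_FIT_ORDER}
        bad = dict(truth, beta=10.0,
                   alpha=nbox.alpha * (1 - np.exp(-nbox.beta * 0.7))
                   / (1 - np.exp(-10.0 * 0.7)))
        free = {k: 0.0 for k in DEFAULT_CONSTRAINT_WEIGHTS}

        def total(params, weights):
            theta = np.array([params[k] for k in _FULL_FIT_ORDER])
            return _full_objective(theta, nbox.tau, sweep, proto.dt, weights)[0]

        # without penalties the two are nearly indistinguishable
        assert total(bad, free) < total(truth, free) + 0.01
        # with the printed weights the unphysical slope is decisively worse
        assert total(bad, None) > total(truth, None) + 50.0


class TestScalingSearchPlumbing:
    def test_transient_removal_precedes_mse(self):
        # a poisoned transient must not affect the objective
        assert M.mse_score(np.zeros(10000), np.r_[np.full(5000, 1e3), np.zeros(5000)],
                           discard=25.0, dt=0.005) == 0.0

    def test_sensitivity_scan_shapes(self, hh, nbox):
        stim = M.ou_process(M.OUSpec(duration=60.0, seed=0))
        empty = sensitivity_scan(hh, nbox, stim, n_samples=0)
        assert len(empty) == 0
        assert list(empty.columns) == ["V_scale", "T_scale", "I_scale", "mse"]
        df = sensitivity_scan(hh, nbox, stim, n_samples=8, seed=1)
        assert len(df) == 8
        assert (df[["V_scale", "T_scale", "I_scale"]].to_numpy() > 0).all()
        assert df.mse.min() > 0

    def test_incumbent_beats_identity_scaling(self, hh, nbox):
        stim = M.ou_process(M.OUSpec(duration=150.0, seed=5))
        truth = M.simulate_hh(hh, M.resting_state(hh), stim)
        sc, fit = fit_scaling(hh, nbox, stim, ground_truth=truth, seed=0,
                              n_restarts=2, max_iter=25)
        try:
            identity_mse = M.mse_score(
                truth["V"],
                M.simulate_hybrid(hh, nbox, M.ScalingFactors.identity(), stim)["V"],
                discard=25.0, dt=0.005)
        except RuntimeError:
            identity_mse = 1e6  # divergent candidates score the penalty value
        assert fit.loss <= identity_mse

    def test_self_consistency_single_seed(self, hh, nbox):
        # ground truth generated by the hybrid model itself is recovered
        truth_sc = M.ScalingFactors.preset("nbox")
        stim = M.ou_process(M.OUSpec(duration=200.0, seed=7))
        gt = M.simulate_hybrid(hh, nbox, truth_sc, stim)
        sc, fit = fit_scaling(hh, nbox, stim, ground_truth=gt, seed=7,
                              n_restarts=4, max_iter=80)
        for a, b in zip(sc.as_tuple(), truth_sc.as_tuple()):
            assert a == pytest.approx(b, rel=0.05)


class TestEvaluateR2:
    def test_model_against_itself_is_one(self, hh):
        stim = M.ou_process(M.OUSpec(duration=100.0, seed=2))
        tr = M.simulate_hh(hh, M.resting_state(hh), stim)
        assert M.r2_score(tr["V"], tr["V"]) == 1.0

    def test_constant_predictor_nonpositive(self, hh, hh_trace):
        const = np.full_like(hh_trace["V"], hh_trace["V"].mean())
        # worse than or equal to predicting the mean
        assert M.r2_score(hh_trace["V"], const) <= 1e-9


def test_fit_result_rejects_negative_loss_terms():
    with pytest.raises(ValueError):
        M.FitResult(params={}, loss=1.0, loss_terms={"mse": -1.0}, steps=1,
                    lr=0.1, seed=0)


def test_reduced_params_validation():
    with pytest.raises(ValueError):
        ReducedModelParams(tau=0.0, A=1.0, G_min=1.0)
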