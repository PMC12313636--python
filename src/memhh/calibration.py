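"""Calibration procedures: device fitting and scaling-factor search.

Three fitting stages mirror how the device model is brought into the neuron:

1. :func:`fit_reduced` - a reduced conductance model
   ``dG/dt = -(G - G_min)/tau + A*[pulse on]`` is fit to a potentiation/decay
   trace to recover the decay constant tau (Adam on exact
   backpropagation-through-time gradients of the unrolled forward-Euler
   simulation).
2. :func:`fit_full` - with tau fixed, the remaining device constants are fit
   to varying-voltage pulse experiments by Adam on finite-difference
   gradients, with soft physical-plausibility penalties
   (:func:`constraint_loss`) added to the current MSE.
3. :func:`fit_scaling` - CMA-ES over log10 of the three passive scaling
   factors, minimizing the post-transient MSE of the hybrid voltage trace
   against an OU-driven Hodgkin-Huxley ground truth simulated with the same
   stimulus realization.

:func:`sensitivity_scan` samples the same objective log-uniformly to expose
the correlated near-optimal valley of the scale space, and
:func:`evaluate_r2` scores an incumbent on a longer held-out horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cmaes import cma_es
from .device import MemristorParams
from .hh import HHParams, resting_state, simulate_hh
from .hybrid import ScalingFactors, simulate_hybrid
from .metrics import mse_score, r2_score
from .synth import OUSpec, ou_process
from .traces import TimeSeriesTrace

__all__ = [
    "ReducedModelParams",
    "FitResult",
    "simulate_reduced",
    "fit_reduced",
    "DEFAULT_CONSTRAINT_WEIGHTS",
    "constraint_loss",
    "fit_full",
    "fit_scaling",
    "sensitivity_scan",
    "evaluate_r2",
]


@dataclass(frozen=True)
class ReducedModelParams:
    """Reduced write-pulse model: decay constant tau (ms), potentiation rate
    A (uS/ms) while the write pulse is on, baseline conductance G_min (uS)."""

    tau: float
    A: float
    G_min: float

    def __post_init__(self) -> None:
        if min(self.tau, self.A, self.G_min) <= 0:
            raise ValueError("all reduced-model parameters must be positive")


@dataclass
class FitResult:
    """Outcome of a fitting run: parameters, loss decomposition, provenance."""

    params: dict
    loss: float
    loss_terms: dict
    steps: int
    lr: float
    seed: int
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.loss_terms.items():
            if v < -1e-12:
                raise ValueError(f"loss component {k} is negative")


def _on_mask(V) -> np.ndarray:
    arr = V["V"] if isinstance(V, TimeSeriesTrace) else np.asarray(V, float)
    return np.ascontiguousarray(arr > 0, dtype=float)


def simulate_reduced(rp: ReducedModelParams, V, dt: float | None = None,
                     G0: float | None = None) -> TimeSeriesTrace:
    """Forward-Euler trajectory of the reduced conductance model.

    ``V`` is the write-voltage waveform (trace or array); the model only
    sees whether the pulse is on.  Initialized at ``G_min`` by default.
    """
    from ._kernels import reduced_model_kernel

    if isinstance(V, TimeSeriesTrace):
        dt = V.dt
    if dt is None or dt <= 0:
        raise ValueError("positive dt required")
    on = _on_mask(V)
    g0 = rp.G_min if G0 is None else float(G0)
    G = reduced_model_kernel(on, dt, rp.tau, rp.A, rp.G_min, g0)
    t = np.arange(on.size) * dt
    return TimeSeriesTrace(t=t, channels={"G": G}, units={"G": "uS"})


def _reduced_loss_and_grad(theta, D, on, dt):
    """MSE loss and its exact BPTT gradient for the reduced model.

    The forward recursion ``G[k+1] = a G[k] + b[k]`` (a = 1 - dt/tau,
    b = dt (G_min/tau + A on)) is linear, so the adjoint recursion is the
    same filter run backwards over the error signal.
    """
    tau, A, G_min = theta
    n = D.size
    a = 1.0 - dt / tau
    b = dt * (G_min / tau + A * on[:-1])
    G = np.empty(n)
    G[0] = G_min
    G[1:] = lfilter([1.0], [1.0, -a], b) + G_min * a ** np.arange(1, n)
    err = G - D
    loss = float(np.mean(err**2))
    e = 2.0 * err / n
    # adjoint p[k] = e[k] + a p[k+1]  (backwards)
    p = lfilter([1.0], [1.0, -a], e[::-1])[::-1]
    p_next = p[1:]  # p[k+1] aligned with transitions k -> k+1
    dA = float(np.sum(p_next * dt * on[:-1]))
    dG_min = float(np.sum(p_next) * dt / tau + p[0])
    dtau = float(np.sum(p_next * (G[:-1] - G_min)) * dt / tau**2)
    return loss, np.array([dtau, dA, dG_min]), G


def fit_reduced(G_data, V, steps: int = 10_000, lr: float = 1e-2, seed: int = 0,
                init: ReducedModelParams | None = None, dt: float | None = None,
                patience: int = 500, rel_tol: float = 1e-10) -> FitResult:
    """Recover (tau, A, G_min) from a potentiation/decay conductance trace.

    Adam on the exact gradient of the unrolled simulation MSE.  ``G_data``
    and ``V`` must be aligned and uniformly sampled.  Returns the
    best-so-far parameters.  The seed only affects the (tiny) jitter used
    when the caller supplies no initial guess.
    """
    if isinstance(G_data, TimeSeriesTrace):
        dt = G_data.dt
        D = np.asarray(G_data["G"], dtype=float)
    else:
        D = np.asarray(G_data, dtype=float)
    if dt is None or dt <= 0:
        raise ValueError("positive dt required")
    on = _on_mask(V)
    if on.size != D.size:
        raise ValueError("G and V traces must be aligned")

    if init is None:
        rng = np.random.default_rng(seed)
        g_lo = float(np.percentile(D, 2))
        g_hi = float(np.percentile(D, 98))
        on_run = np.flatnonzero(np.diff(np.concatenate(([0.0], on))) > 0)
        # crude on-duration estimate from the first pulse
        if on_run.size:
            k0 = on_run[0]
            k1 = k0
            while k1 < on.size and on[k1] > 0:
                k1 += 1
            t_on = (k1 - k0) * dt
        else:
            t_on = 1.0
        theta = np.array([
            20.0,
            max((g_hi - g_lo) / max(t_on, dt), 1e-3),
            max(g_lo, 1e-3),
        ]) * (1.0 + 1e-3 * rng.standard_normal(3))
    else:
        theta = np.array([init.tau, init.A, init.G_min], dtype=float)

    m = np.zeros(3)
    v = np.zeros(3)
    b1, b2, eps = 0.9, 0.999, 1e-8
    best = (np.inf, theta.copy())
    floor = np.array([1e-3, 1e-6, 1e-6])
    anchor_loss, anchor_step = np.inf, 0
    for t_step in range(1, steps + 1):
        loss, grad, _ = _reduced_loss_and_grad(theta, D, on, dt)
        if not math.isfinite(loss):
            raise RuntimeError("non-finite loss in fit_reduced")
        if loss < best[0]:
            best = (loss, theta.copy())
        if t_step - anchor_step >= patience:
            if anchor_loss - best[0] < rel_tol * max(anchor_loss, 1e-30):
                break
            anchor_loss, anchor_step = best[0], t_step
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        mh = m / (1 - b1**t_step)
        vh = v / (1 - b2**t_step)
        theta = np.maximum(theta - lr * mh / (np.sqrt(vh) + eps), floor)

    loss, _, _ = _reduced_loss_and_grad(best[1], D, on, dt)
    tau, A, G_min = best[1]
    return FitResult(
        params={"tau": float(tau), "A": float(A), "G_min": float(G_min)},
        loss=float(loss),
        loss_terms={"mse": float(loss)},
        steps=steps,
        lr=lr,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Full-model fit

#: Soft-constraint weights: anchors on w_min (near 0.15) and beta (near 0.5),
#: a trajectory-overshoot penalty, and non-negativity barriers.
DEFAULT_CONSTRAINT_WEIGHTS = {
    "w_min_anchor": 1e3,     # (w_min - 0.15)^2
    "overshoot": 1e2,        # sum_t w H(w - 1)
    "nonneg": 1e4,           # |theta| H(-theta) for alpha, beta, gamma, w_min, lam, eta
    "beta_anchor": 1.0,      # (beta - 0.5)^2
    "read_current": 0.0,     # (i(w_min, V_read) - V_read * G_target)^2, off by default
}


def constraint_loss(params, w_trajectory=None, weights: dict | None = None,
                    read_voltage: float = 0.7, G_target: float = 2.18) -> tuple[float, dict]:
    """Weighted physical-plausibility penalties for the full-model fit.

    ``params`` may be a :class:`MemristorParams` or a raw dict with the same
    field names (raw dicts allow transiently infeasible optimizer iterates).
    Returns ``(total, per-term breakdown)``; zero iff every constraint is
    satisfied exactly (anchors included).
    """
    w = dict(DEFAULT_CONSTRAINT_WEIGHTS)
    if weights:
        w.update(weights)
    p = params.to_dict() if isinstance(params, MemristorParams) else dict(params)
    terms = {}
    terms["w_min_anchor"] = w["w_min_anchor"] * (p["w_min"] - 0.15) ** 2
    terms["beta_anchor"] = w["beta_anchor"] * (p["beta"] - 0.5) ** 2
    nonneg = 0.0
    for name in ("alpha", "beta", "gamma", "w_min", "lam", "eta"):
        val = p[name]
        if val < 0:
            nonneg += abs(val)
    terms["nonneg"] = w["nonneg"] * nonneg
    if w_trajectory is not None:
        wt = np.asarray(w_trajectory, dtype=float)
        terms["overshoot"] = w["overshoot"] * float(np.sum(wt[wt > 1.0]))
    else:
        terms["overshoot"] = 0.0
    if w["read_current"] > 0:
        i_read = ((1 - p["w_min"]) * p["alpha"] * (1 - math.exp(-p["beta"] * read_voltage))
                  + p["w_min"] * p["gamma"] * math.sinh(p["delta"] * read_voltage))
        terms["read_current"] = w["read_current"] * (i_read - read_voltage * G_target) ** 2
    else:
        terms["read_current"] = 0.0
    return float(sum(terms.values())), terms


_FULL_FIT_ORDER = ("alpha", "beta", "gamma", "delta", "eta", "lam", "w_min")


def _full_objective(theta, tau, sweep, dt, weights):
    """Current MSE over the pulse-sweep traces plus constraint penalties."""
    from ._kernels import device_state_kernel

    p = dict(zip(_FULL_FIT_ORDER, theta))
    w_min = min(p["w_min"], 0.98)
    pm = np.array([tau, p["alpha"], p["beta"], p["gamma"], p["delta"],
                   p["eta"], p["lam"], w_min, 0.99])
    sq_sum = 0.0
    n_tot = 0
    overshoot = 0.0
    for v_arr, v_meas, i_data in sweep:
        w = device_state_kernel(v_arr, dt, pm, w_min)
        i_model = ((1.0 - w) * pm[1] * (1.0 - np.exp(-np.clip(pm[2] * v_meas, -40, 40)))
                   + w * pm[3] * np.sinh(np.clip(pm[4] * v_meas, -40, 40)))
        sq_sum += float(np.sum((i_model - i_data) ** 2))
        n_tot += i_data.size
    mse = sq_sum / n_tot
    pen, terms = constraint_loss(dict(p, tau=tau, delta=p["delta"]), None, weights)
    terms["mse"] = mse
    return mse + pen, terms


def fit_full(sweep_traces, tau: float, steps: int = 50_000, lr: float = 1e-3,
             seed: int = 0, init: dict | None = None, weights: dict | None = None,
             patience: int = 1000, rel_tol: float = 1e-8,
             lr_decay: float = 0.5, min_lr_factor: float = 1e-2) -> FitResult:
    """Fit the full device law to varying-voltage pulse experiments.

    ``sweep_traces`` are traces with channels ``V`` (applied voltage),
    ``V_meas`` (measurement bias) and ``i`` (recorded current), as produced
    by :func:`memhh.synth.generate_pulse_sweep`.  ``tau`` is held fixed (it
    comes from the reduced fit).  Adam on central finite-difference
    gradients.  When the relative loss improvement over ``patience`` steps
    falls below ``rel_tol`` the learning rate is decayed by ``lr_decay``
    (the loss valley around the optimum is shallow along the
    gamma / w_min degeneracy and needs a fine final step size); the run
    stops once stalled at ``lr * min_lr_factor``.  On a non-finite loss the
    last finite incumbent is returned with ``converged=False``.
    """
    dt = sweep_traces[0].dt
    sweep = [
        (np.ascontiguousarray(tr["V"]), np.asarray(tr["V_meas"]), np.asarray(tr["i"]))
        for tr in sweep_traces
    ]
    rng = np.random.default_rng(seed)
    if init is None:
        init = {"alpha": 0.05, "beta": 0.5, "gamma": 5.0, "delta": 1.0,
                "eta": 1.0, "lam": 0.01, "w_min": 0.15}
    theta = np.array([init[k] for k in _FULL_FIT_ORDER], dtype=float)
    theta *= 1.0 + 1e-4 * rng.standard_normal(theta.size)

    def objective(th):
        return _full_objective(th, tau, sweep, dt, weights)

    m = np.zeros(theta.size)
    v = np.zeros(theta.size)
    b1, b2, eps = 0.9, 0.999, 1e-8
    best_loss, best_theta = np.inf, theta.copy()
    anchor_loss, anchor_step = np.inf, 0
    converged = True
    steps_run = 0
    cur_lr = lr
    for t_step in range(1, steps + 1):
        steps_run = t_step
        loss, _ = objective(theta)
        if not math.isfinite(loss):
            converged = False
            break
        if loss < best_loss:
            best_loss, best_theta = loss, theta.copy()
        # on stalled improvement: decay the step size, then stop
        if t_step - anchor_step >= patience:
            if anchor_loss - best_loss < rel_tol * max(anchor_loss, 1e-30):
                cur_lr *= lr_decay
                theta = best_theta.copy()
                if cur_lr < lr * min_lr_factor:
                    break
            anchor_loss, anchor_step = best_loss, t_step
        grad = np.empty(theta.size)
        for j in range(theta.size):
            h = 1e-6 * (abs(theta[j]) + 1e-3)
            tp = theta.copy(); tp[j] += h
            tm = theta.copy(); tm[j] -= h
            lp, _ = objective(tp)
            lm, _ = objective(tm)
            grad[j] = (lp - lm) / (2 * h)
        m = b1 * m + (1 - b1) * grad
        v = b2 * v + (1 - b2) * grad**2
        mh = m / (1 - b1**t_step)
        vh = v / (1 - b2**t_step)
        theta = theta - cur_lr * mh / (np.sqrt(vh) + eps)

    loss, terms = objective(best_theta)
    params = dict(zip(_FULL_FIT_ORDER, (float(x) for x in best_theta)))
    params["tau"] = float(tau)
    return FitResult(
        params=params,
        loss=float(loss),
        loss_terms={k: float(v) for k, v in terms.items()},
        steps=steps_run,
        lr=lr,
        seed=seed,
        converged=converged,
        meta={"fixed": {"tau": float(tau)}, "patience": patience, "rel_tol": rel_tol},
    )


# ---------------------------------------------------------------------------
# Scaling-factor search


def _scale_objective_factory(hh, mem, iapp, truth_V, dt, discard, law):
    def objective(z):
        scales = ScalingFactors(*(10.0**np.asarray(z, dtype=float)))
        try:
            tr = simulate_hybrid(hh, mem, scales, iapp, dt=dt, law=law)
        except RuntimeError:
            return 1e6
        return mse_score(truth_V, tr["V"], discard=discard, dt=dt)
    return objective


def fit_scaling(hh: HHParams, mem: MemristorParams, stimulus, ground_truth=None,
                dt: float = 0.005, discard: float = 25.0, bounds=(1e-3, 1e3),
                seed: int = 0, sigma0: float = 1.0, popsize: int | None = None,
                max_iter: int = 80, x0=None, n_restarts: int = 6,
                law: str = "sinh") -> tuple[ScalingFactors, FitResult]:
    """CMA-ES search for (V_scale, T_scale, I_scale) in log10 space.

    ``stimulus`` is the OU current trace shared by ground truth and every
    candidate; ``ground_truth`` defaults to the HH simulation itself.  The
    objective is the voltage MSE after discarding the first ``discard`` ms.
    Candidates whose simulation diverges score 1e6 (plus the out-of-bounds
    penalty of the optimizer).

    The MSE landscape is multimodal - a broad basin of silent (non-spiking)
    traces competes with a narrower basin of co-spiking solutions - so the
    search restarts CMA-ES from ``n_restarts`` start points (the supplied
    ``x0``, identity scales, and randomized points drawn within the central
    decades of the box) and keeps the best incumbent overall.  Returns the
    incumbent scales and a :class:`FitResult` with optimizer provenance.
    """
    from .hh import _stimulus_array

    iapp = _stimulus_array(stimulus, dt)
    if ground_truth is None:
        ground_truth = simulate_hh(hh, resting_state(hh), iapp, dt=dt)
    truth_V = np.asarray(
        ground_truth["V"] if isinstance(ground_truth, TimeSeriesTrace) else ground_truth,
        dtype=float,
    )
    objective = _scale_objective_factory(hh, mem, iapp, truth_V, dt, discard, law)
    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])

    rng = np.random.default_rng(seed)
    z_first = np.zeros(3) if x0 is None else np.log10(np.asarray(x0, dtype=float))
    # coarse randomized scan; its best points seed tight local refinements
    scan = rng.uniform(-2.0, 2.0, size=(128, 3))
    scan_f = np.array([objective(np.clip(z, lo, hi)) for z in scan])
    # restart schedule: one explorative large-population run from x0, tight
    # runs from the scan leaders, then randomized medium runs
    big_pop = popsize if popsize is not None else 16
    starts = [(z_first, sigma0, big_pop)]
    for idx in np.argsort(scan_f)[:2]:
        starts.append((scan[idx], 0.3 * sigma0, popsize))
    while len(starts) < max(1, n_restarts):
        starts.append((rng.uniform(-2.0, 2.0, size=3), sigma0, popsize))

    best_res = None
    restart_log = []
    for z0, sig, pop in starts:
        res = cma_es(
            objective,
            x0=z0,
            sigma0=sig,
            bounds=(np.full(3, lo), np.full(3, hi)),
            popsize=pop,
            max_iter=max_iter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        restart_log.append({"x0": [float(v) for v in z0], "f": res.fun,
                            "x": [float(v) for v in 10.0**res.x]})
        if best_res is None or res.fun < best_res.fun:
            best_res = res
    # polish the incumbent with a tight local run
    polish = cma_es(
        objective,
        x0=np.log10(10.0**best_res.x),
        sigma0=0.05,
        bounds=(np.full(3, lo), np.full(3, hi)),
        popsize=popsize,
        max_iter=max_iter,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    res = polish if polish.fun < best_res.fun else best_res
    scales = ScalingFactors(*(10.0**res.x))
    fit = FitResult(
        params={"V_scale": scales.V_scale, "T_scale": scales.T_scale,
                "I_scale": scales.I_scale},
        loss=res.fun,
        loss_terms={"mse": res.fun},
        steps=res.n_iter,
        lr=float("nan"),
        seed=seed,
        meta={"n_evals": res.n_evals, "sigma0": sigma0, "bounds": list(bounds),
              "discard_ms": discard, "restarts": restart_log},
    )
    return scales, fit


def sensitivity_scan(hh: HHParams, mem: MemristorParams, stimulus, ground_truth=None,
                     n_samples: int = 200, ranges=((1e-3, 1e3),) * 3,
                     dt: float = 0.005, discard: float = 25.0, seed: int = 0,
                     law: str = "sinh") -> pd.DataFrame:
    """Log-uniform random scan of the scaling space with MSE scores.

    Returns a DataFrame with columns V_scale, T_scale, I_scale, mse - the
    raw material for threshold/correlation summaries of the near-optimal
    valley.
    """
    from .hh import _stimulus_array

    iapp = _stimulus_array(stimulus, dt)
    if ground_truth is None and n_samples > 0:
        ground_truth = simulate_hh(hh, resting_state(hh), iapp, dt=dt)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_samples):
        z = [rng.uniform(math.log10(lo), math.log10(hi)) for lo, hi in ranges]
        scales = ScalingFactors(*(10.0**np.asarray(z)))
        try:
            tr = simulate_hybrid(hh, mem, scales, iapp, dt=dt, law=law)
            truth_V = np.asarray(
                ground_truth["V"] if isinstance(ground_truth, TimeSeriesTrace) else ground_truth
            )
            mse = mse_score(truth_V, tr["V"], discard=discard, dt=dt)
        except RuntimeError:
            mse = float("inf")
        rows.append({"V_scale": scales.V_scale, "T_scale": scales.T_scale,
                     "I_scale": scales.I_scale, "mse": mse})
    return pd.DataFrame(rows, columns=["V_scale", "T_scale", "I_scale", "mse"])


def evaluate_r2(hh: HHParams, mem: MemristorParams, scales: ScalingFactors,
                ou: OUSpec, horizon_multiplier: float = 5.0, discard: float = 25.0,
                law: str = "sinh") -> float:
    """R^2 of the hybrid voltage against HH over an extended horizon.

    The OU spec's duration is stretched by ``horizon_multiplier`` (same
    seed), both models are driven by the identical realization, and the
    post-transient coefficient of determination is returned (<= 1).
    """
    from dataclasses import replace

    long_ou = replace(ou, duration=ou.duration * horizon_multiplier)
    stim = ou_process(long_ou)
    truth = simulate_hh(hh, resting_state(hh), stim, dt=long_ou.dt)
    test = simulate_hybrid(hh, mem, scales, stim, dt=long_ou.dt, law=law)
    return r2_score(truth["V"], test["V"], discard=discard, dt=long_ou.dt)
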