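"""Canonical Hodgkin-Huxley squid-axon neuron (the reference ground truth).

Membrane equation (current densities in uA/cm^2, voltages in mV, time in ms)::

    C_m dV/dt = i_app - g_Na m^3 h (V - E_Na) - g_K n^4 (V - E_K) - g_L (V - E_L)

with first-order gate kinetics ``dx/dt = alpha_x(V) (1 - x) - beta_x(V) x``
for x in {n, m, h}, using the classic rate functions in the modern voltage
convention (rest near -65 mV).  The potassium branch ``g_K n^4 (V - E_K)``
is the element the memristor emulates: under oscillatory bias it traces a
pinched hysteresis loop in the (V - E_K, i) plane, the fingerprint of a
voltage-controlled volatile memristor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .traces import TimeSeriesTrace

__all__ = [
    "HHParams",
    "HHState",
    "gate_rates",
    "n_inf",
    "tau_n",
    "hh_derivatives",
    "resting_state",
    "simulate_hh",
    "k_channel_current",
]


@dataclass(frozen=True)
class HHParams:
    """Passive and maximal-conductance constants of the squid-axon model."""

    C_m: float = 1.0      # uF/cm^2
    g_Na: float = 120.0   # mS/cm^2
    g_K: float = 36.0     # mS/cm^2
    g_L: float = 0.3      # mS/cm^2
    E_Na: float = 50.0    # mV
    E_K: float = -77.0    # mV
    E_L: float = -54.4    # mV

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be nonnegative")
        if not (self.E_Na > self.E_L > self.E_K):
            raise ValueError("expected E_Na > E_L > E_K")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.C_m, self.g_Na, self.g_K, self.g_L, self.E_Na, self.E_K, self.E_L]
        )


@dataclass
class HHState:
    V: float   # mV
    n: float
    m: float
    h: float

    def __post_init__(self) -> None:
        for g in (self.n, self.m, self.h):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gating variables must lie in [0, 1]")


def _trap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity filled by its limit."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)  # avoid 0/0 in the generic branch
    out = np.where(small, y + 0.5 * x,
                   safe / (1.0 - np.exp(-np.clip(safe / y, -500, 500))))
    return out


def gate_rates(V):
    """Opening/closing rates (1/ms) of the n, m and h gates at voltage V (mV)."""
    V = np.asarray(V, dtype=float)
    a_n = 0.01 * _trap(V + 55.0, 10.0)
    b_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    a_m = 0.1 * _trap(V + 40.0, 10.0)
    b_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    return a_n, b_n, a_m, b_m, a_h, b_h


def n_inf(V):
    """Steady-state activation of the potassium gate (monotone sigmoid)."""
    a, b, *_ = gate_rates(V)
    return a / (a + b)


def tau_n(V):
    """Relaxation time (ms) of the potassium gate."""
    a, b, *_ = gate_rates(V)
    return 1.0 / (a + b)


def hh_derivatives(p: HHParams, s: HHState, i_app: float = 0.0):
    """Right-hand side (dV/dt, dn/dt, dm/dt, dh/dt) of the HH ODEs."""
    a_n, b_n, a_m, b_m, a_h, b_h = gate_rates(s.V)
    i_na = p.g_Na * s.m**3 * s.h * (s.V - p.E_Na)
    i_k = p.g_K * s.n**4 * (s.V - p.E_K)
    i_l = p.g_L * (s.V - p.E_L)
    dV = (i_app - i_na - i_k - i_l) / p.C_m
    return (
        float(dV),
        float(a_n * (1 - s.n) - b_n * s.n),
        float(a_m * (1 - s.m) - b_m * s.m),
        float(a_h * (1 - s.h) - b_h * s.h),
    )


def _x_inf(V):
    a_n, b_n, a_m, b_m, a_h, b_h = gate_rates(V)
    return a_n / (a_n + b_n), a_m / (a_m + b_m), a_h / (a_h + b_h)


def resting_state(p: HHParams, i_app: float = 0.0) -> HHState:
    """Fixed point of the HH system at constant applied current (root find)."""

    def residual(V):
        n, m, h = _x_inf(V)
        return (
            i_app
            - p.g_Na * m**3 * h * (V - p.E_Na)
            - p.g_K * n**4 * (V - p.E_K)
            - p.g_L * (V - p.E_L)
        )

    V = brentq(residual, p.E_K + 1e-6, p.E_Na - 1e-6, xtol=1e-10)
    n, m, h = _x_inf(V)
    return HHState(V=float(V), n=float(n), m=float(m), h=float(h))


def _stimulus_array(stimulus, dt: float) -> np.ndarray:
    if isinstance(stimulus, TimeSeriesTrace):
        if not math.isclose(stimulus.dt, dt, rel_tol=1e-9):
            raise ValueError(f"stimulus dt {stimulus.dt} does not match integrator dt {dt}")
        return np.ascontiguousarray(stimulus["i_app"], dtype=float)
    return np.ascontiguousarray(stimulus, dtype=float)


def simulate_hh(p: HHParams, init: HHState | None, stimulus, dt: float = 0.005) -> TimeSeriesTrace:
    """Integrate the HH neuron under an applied-current waveform.

    ``stimulus`` is either a :class:`TimeSeriesTrace` with channel ``i_app``
    sampled at ``dt``, or a plain array of current densities (uA/cm^2).
    Deterministic given the stimulus realization (noise, if any, lives in
    the stimulus itself); forward-Euler / Euler-Maruyama stepping.
    """
    from ._kernels import hh_kernel

    if dt <= 0:
        raise ValueError("dt must be positive")
    iapp = _stimulus_array(stimulus, dt)
    if init is None:
        init = resting_state(p)
    V, n, m, h = hh_kernel(iapp, dt, p.as_array(), init.V, init.n, init.m, init.h)
    t = np.arange(iapp.size) * dt
    return TimeSeriesTrace(
        t=t,
        channels={"V": V, "n": n, "m": m, "h": h, "i_app": iapp},
        units={"V": "mV", "i_app": "uA_per_cm2"},
    )


def k_channel_current(p: HHParams, s: HHState | None = None, V=None, n=None):
    """Potassium-channel current density g_K n^4 (V - E_K) in uA/cm^2.

    Accepts either an :class:`HHState` or explicit (V, n) arrays; zero at
    V = E_K for any gate value.
    """
    if s is not None:
        V, n = s.V, s.n
    V = np.asarray(V, dtype=float)
    n = np.asarray(n, dtype=float)
    out = p.g_K * n**4 * (V - p.E_K)
    return float(out) if out.ndim == 0 else out
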