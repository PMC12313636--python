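"""Memristor-emulated Hodgkin-Huxley neuron.

The potassium branch of the HH circuit is replaced by the volatile memristor,
bridged by three positive scaling factors that map between biological model
units and physical device units:

* ``V_scale`` (volt/mV): device voltage is ``V_scale * (v - E_K)``,
* ``T_scale`` (ms/ms): the device state equation runs ``T_scale`` times
  faster than biological time,
* ``I_scale`` (uA per uA/cm^2): the device current ``i_dev`` enters the
  membrane equation as the current density ``I_scale * i_dev``.

In hardware the same three numbers correspond to re-scaling the passive
components (membrane capacitance, reversal-potential sources and the leak
resistor) rather than touching the device; :func:`scale_passive` computes
those component values and :func:`simulate_scaled_circuit` integrates the
physical circuit directly, which must reproduce the unit-space simulation
exactly under the variable change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .device import MemristorParams, device_current, linear_variant_current, state_rate, steady_state_w
from .hh import HHParams, k_channel_current, n_inf, resting_state
from .traces import TimeSeriesTrace

__all__ = [
    "ScalingFactors",
    "HybridState",
    "memristor_k_current",
    "memristor_k_rate",
    "simulate_hybrid",
    "hybrid_resting_state",
    "scale_passive",
    "simulate_scaled_circuit",
    "steady_state_comparison",
    "DIVERGENCE_GUARD_MV",
]

#: |V| beyond this (mV) aborts a hybrid simulation as numerically divergent.
DIVERGENCE_GUARD_MV = 500.0


@dataclass(frozen=True)
class ScalingFactors:
    """Voltage/time/current re-scaling between HH units and device units."""

    V_scale: float  # volt/mV
    T_scale: float  # ms/ms
    I_scale: float  # uA per uA/cm^2

    def __post_init__(self) -> None:
        if min(self.V_scale, self.T_scale, self.I_scale) <= 0:
            raise ValueError("all scaling factors must be strictly positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.V_scale, self.T_scale, self.I_scale)

    @classmethod
    def identity(cls) -> "ScalingFactors":
        return cls(1.0, 1.0, 1.0)

    @classmethod
    def preset(cls, name: str) -> "ScalingFactors":
        """Published best-fit scales for ``"nbox"`` or ``"wox"``."""
        text = resources.files("memhh.presets").joinpath("scales.json").read_text()
        table = json.loads(text)
        if name.lower() not in table:
            raise KeyError(f"unknown scaling preset {name!r}; available: {sorted(table)}")
        return cls(**table[name.lower()])


@dataclass
class HybridState:
    V: float  # mV
    m: float
    h: float
    w: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError("gating variables must lie in [0, 1]")


def memristor_k_current(p: MemristorParams, s: ScalingFactors, w, v, E_K: float,
                        law: str = "sinh"):
    """Emulated potassium current density (uA/cm^2) at membrane voltage v (mV).

    ``I_scale * i_dev(w, V_scale * (v - E_K))``; zero at v = E_K for any w.
    """
    fn = device_current if law == "sinh" else linear_variant_current
    return s.I_scale * fn(p, w, s.V_scale * (np.asarray(v, float) - E_K))


def memristor_k_rate(p: MemristorParams, s: ScalingFactors, w, v, E_K: float):
    """State velocity dw/dt (1/ms of biological time) of the emulated channel."""
    return s.T_scale * state_rate(p, w, s.V_scale * (np.asarray(v, float) - E_K))


def _device_law_flag(law: str) -> bool:
    if law not in ("sinh", "linear"):
        raise ValueError(f"unknown device law {law!r} (expected 'sinh' or 'linear')")
    return law == "linear"


def simulate_hybrid(hh: HHParams, mem: MemristorParams, s: ScalingFactors, stimulus,
                    dt: float = 0.005, init: HybridState | None = None,
                    law: str = "sinh") -> TimeSeriesTrace:
    """Integrate the hybrid neuron (V, m, h, w) under an applied-current waveform.

    Defaults follow the study conditions: forward-Euler / Euler-Maruyama at
    dt = 0.005 ms from V(0) = -60 mV, w(0) = w_min, sodium gates at their
    steady state for V(0).  Raises RuntimeError if |V| exceeds the 500-mV
    divergence guard.  ``law="linear"`` swaps in the linear-conductance
    device variant (state dynamics unchanged).
    """
    from ._kernels import hybrid_kernel
    from .hh import _stimulus_array, gate_rates

    if dt <= 0:
        raise ValueError("dt must be positive")
    iapp = _stimulus_array(stimulus, dt)
    if init is None:
        v0 = -60.0
        _, _, a_m, b_m, a_h, b_h = gate_rates(v0)
        init = HybridState(V=v0, m=float(a_m / (a_m + b_m)), h=float(a_h / (a_h + b_h)),
                           w=mem.w_min)
    V, m, h, w, abort = hybrid_kernel(
        iapp, dt, hh.as_array(), mem.as_array(), s.V_scale, s.T_scale, s.I_scale,
        _device_law_flag(law), init.V, init.m, init.h, init.w, DIVERGENCE_GUARD_MV,
    )
    if abort >= 0:
        raise RuntimeError(
            f"hybrid simulation diverged: |V| > {DIVERGENCE_GUARD_MV} mV at "
            f"t = {abort * dt:.3f} ms (scales {s.as_tuple()})"
        )
    t = np.arange(iapp.size) * dt
    return TimeSeriesTrace(
        t=t,
        channels={"V": V, "m": m, "h": h, "w": w, "i_app": iapp},
        units={"V": "mV", "i_app": "uA_per_cm2"},
    )


def hybrid_resting_state(hh: HHParams, mem: MemristorParams, s: ScalingFactors,
                         law: str = "sinh") -> HybridState:
    """Quiescent fixed point of the hybrid neuron (w at its bias steady state)."""
    from scipy.optimize import brentq
    from .hh import gate_rates

    def residual(v):
        w = steady_state_w(mem, s.V_scale * (v - hh.E_K))
        i_k = memristor_k_current(mem, s, w, v, hh.E_K, law=law)
        _, _, a_m, b_m, a_h, b_h = gate_rates(v)
        m = a_m / (a_m + b_m)
        h = a_h / (a_h + b_h)
        return -hh.g_Na * m**3 * h * (v - hh.E_Na) - i_k - hh.g_L * (v - hh.E_L)

    v = brentq(residual, hh.E_K + 1e-9, hh.E_Na, xtol=1e-10)
    _, _, a_m, b_m, a_h, b_h = gate_rates(v)
    return HybridState(
        V=float(v),
        m=float(a_m / (a_m + b_m)),
        h=float(a_h / (a_h + b_h)),
        w=float(steady_state_w(mem, s.V_scale * (v - hh.E_K))),
    )


def scale_passive(hh: HHParams, s: ScalingFactors) -> dict[str, float]:
    """Physical passive-component values realizing the scaled hybrid circuit.

    Convention: physical branch currents are the device's own microamperes
    (``i_phys = i_model / I_scale``), voltages are ``V_scale`` times the
    biological millivolts, and physical time runs ``T_scale`` times slower
    than biological time (``t_phys = t_bio / T_scale``).  Circuit
    equivalence then fixes::

        E'_x = V_scale * E_x                            (volts)
        R'_L = V_scale * I_scale * R_L                  (V/uA, R_L = 1/g_L)
        g'_Na = g_Na / (V_scale * I_scale)              (uA/V)
        C'_m = C_m * T_scale / (V_scale * I_scale)      (uA*ms/V)

    Physical time runs ``t_phys = T_scale * t_bio`` - the device's native
    decay constant tau (physical ms) corresponds to ``tau / T_scale``
    biological ms, which is what the state equation's T_scale prefactor
    expresses in unit space.
    """
    return {
        "E_Na_volts": s.V_scale * hh.E_Na,
        "E_K_volts": s.V_scale * hh.E_K,
        "E_L_volts": s.V_scale * hh.E_L,
        "R_L_V_per_uA": s.V_scale * s.I_scale / hh.g_L,
        "g_Na_uA_per_V": hh.g_Na / (s.V_scale * s.I_scale),
        "C_m_uA_ms_per_V": hh.C_m * s.T_scale / (s.V_scale * s.I_scale),
    }


def simulate_scaled_circuit(hh: HHParams, mem: MemristorParams, s: ScalingFactors,
                            stimulus, dt: float = 0.005,
                            init: HybridState | None = None,
                            law: str = "sinh") -> TimeSeriesTrace:
    """Integrate the physically re-scaled circuit in device units.

    ``stimulus`` is the *biological* current-density waveform sampled at the
    *biological* step ``dt``; it is converted to physical device current
    internally.  The returned trace has physical time (ms) and voltage
    (volts).  Converting it back with ``V / V_scale`` and ``t * ...`` must
    match :func:`simulate_hybrid` sample for sample - the round-trip test of
    the passive-scaling convention.
    """
    from ._kernels import scaled_circuit_kernel
    from .hh import _stimulus_array, gate_rates

    comp = scale_passive(hh, s)
    iapp_bio = _stimulus_array(stimulus, dt)
    iapp_phys = np.ascontiguousarray(iapp_bio / s.I_scale)
    dt_phys = dt * s.T_scale
    if init is None:
        v0 = -60.0
        _, _, a_m, b_m, a_h, b_h = gate_rates(v0)
        init = HybridState(V=v0, m=float(a_m / (a_m + b_m)), h=float(a_h / (a_h + b_h)),
                           w=mem.w_min)
    V, m, h, w = scaled_circuit_kernel(
        iapp_phys, dt_phys, comp["C_m_uA_ms_per_V"], comp["g_Na_uA_per_V"],
        comp["R_L_V_per_uA"], comp["E_Na_volts"], comp["E_K_volts"], comp["E_L_volts"],
        mem.as_array(), _device_law_flag(law),
        s.V_scale * init.V, init.m, init.h, init.w, s.T_scale, s.V_scale,
    )
    t = np.arange(iapp_phys.size) * dt_phys
    return TimeSeriesTrace(
        t=t,
        channels={"V": V, "m": m, "h": h, "w": w, "i_app": iapp_phys},
        units={"V": "volts", "i_app": "uA"},
    )


def steady_state_comparison(hh: HHParams, mem: MemristorParams, s: ScalingFactors,
                            v_grid=None, law: str = "sinh") -> dict[str, np.ndarray]:
    """Steady-state I-V of the native K channel vs. its memristor emulation.

    For each membrane voltage v: the HH current ``g_K n_inf(v)^4 (v - E_K)``
    and the emulated current at ``w = w_inf(V_scale (v - E_K))``.  Both are
    zero at v = E_K; the sinh tunneling term makes the memristor branch grow
    super-linearly at large depolarization.
    """
    if v_grid is None:
        v_grid = np.linspace(hh.E_K, 60.0, 200)
    v_grid = np.asarray(v_grid, dtype=float)
    i_hh = k_channel_current(hh, V=v_grid, n=n_inf(v_grid))
    w_inf = steady_state_w(mem, s.V_scale * (v_grid - hh.E_K))
    i_mem = memristor_k_current(mem, s, w_inf, v_grid, hh.E_K, law=law)
    return {"v": v_grid, "i_K_hh": np.asarray(i_hh), "i_K_mem": np.asarray(i_mem)}
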