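"""Multi-compartment axon of memristor-emulated neurons, and F-I analysis.

A chain of hybrid compartments (default 30) coupled by a nearest-neighbour
axial conductance, with sealed ends (end compartments have a single
neighbour and no extra leak).  The stimulus is injected into the first
compartment only; a suprathreshold input there launches a spike wave that
propagates down the chain despite the reduced spike amplitude of the
memristor-emulated channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device import MemristorParams
from .hh import HHParams, gate_rates, resting_state, simulate_hh
from .hybrid import DIVERGENCE_GUARD_MV, ScalingFactors, simulate_hybrid
from .metrics import detect_spikes
from .traces import TimeSeriesTrace

__all__ = ["AxonConfig", "simulate_axon", "propagation_metrics", "fi_curve"]


@dataclass(frozen=True)
class AxonConfig:
    """Chain geometry: compartment count, axial coupling conductance
    (mS/cm^2) and the index of the stimulated compartment.

    The default coupling sits in the middle of the propagation-success
    region found by a one-dimensional sweep for the NbOx-tuned neuron.
    """

    n_compartments: int = 30
    g_axial: float = 0.5
    stimulus_target: int = 0

    def __post_init__(self) -> None:
        if self.n_compartments < 2:
            raise ValueError("need at least two compartments")
        if self.g_axial <= 0:
            raise ValueError("g_axial must be positive")
        if not 0 <= self.stimulus_target < self.n_compartments:
            raise ValueError("stimulus target out of range")


def simulate_axon(cfg: AxonConfig, hh: HHParams, mem: MemristorParams,
                  s: ScalingFactors, stimulus, dt: float = 0.005,
                  law: str = "sinh", v0: float = -60.0) -> TimeSeriesTrace:
    """Integrate the coupled chain; returns a trace with matrix channels
    ``V`` and ``w`` of shape (n_samples, n_compartments)."""
    from ._kernels import axon_kernel
    from .hh import _stimulus_array

    if cfg.stimulus_target != 0:
        raise NotImplementedError("stimulus is injected into compartment 0")
    iapp = _stimulus_array(stimulus, dt)
    ncomp = cfg.n_compartments
    _, _, a_m, b_m, a_h, b_h = gate_rates(v0)
    V0 = np.full(ncomp, float(v0))
    m0 = np.full(ncomp, float(a_m / (a_m + b_m)))
    h0 = np.full(ncomp, float(a_h / (a_h + b_h)))
    w0 = np.full(ncomp, mem.w_min)
    V, W, abort = axon_kernel(
        iapp, dt, hh.as_array(), mem.as_array(), s.V_scale, s.T_scale, s.I_scale,
        law == "linear", cfg.g_axial, V0, m0, h0, w0, DIVERGENCE_GUARD_MV,
    )
    if abort >= 0:
        raise RuntimeError(f"axon simulation diverged at t = {abort * dt:.3f} ms")
    t = np.arange(iapp.size) * dt
    return TimeSeriesTrace(t=t, channels={"V": V, "w": W, "i_app": iapp},
                           units={"V": "mV", "i_app": "uA_per_cm2"})


def propagation_metrics(trace: TimeSeriesTrace, threshold: float = -30.0,
                        refractory: float = 2.0, window: float = 150.0):
    """Did a spike wave reach the end of the chain, and how fast?

    Returns ``(propagated, delays)`` where ``delays[j]`` is the first spike
    time of compartment j minus that of compartment 0 (NaN if silent).
    ``propagated`` requires every compartment to spike within ``window`` ms
    of compartment 0's first spike.
    """
    V = np.asarray(trace["V"])
    if V.ndim != 2:
        raise ValueError("expected a matrix voltage channel (time x compartment)")
    ncomp = V.shape[1]
    first = np.full(ncomp, np.nan)
    for j in range(ncomp):
        st = detect_spikes(V[:, j], threshold=threshold, refractory=refractory,
                           dt=trace.dt)
        if st.count:
            first[j] = st.times[0]
    if np.isnan(first[0]):
        return False, first
    delays = first - first[0]
    propagated = bool(np.all(np.isfinite(delays)) and np.all(delays <= window))
    return propagated, delays


def fi_curve(model: str, hh: HHParams, currents, duration: float = 500.0,
             dt: float = 0.005, mem: MemristorParams | None = None,
             scales: ScalingFactors | None = None, law: str = "sinh",
             threshold: float = -30.0, refractory: float = 2.0,
             discard: float = 50.0):
    """Firing rate (Hz) versus constant applied current.

    ``model`` is ``"hh"`` or ``"hybrid"`` (the latter needs ``mem`` and
    ``scales``).  Spikes are counted after an initial ``discard`` ms so the
    onset transient does not bias the rate.  Returns (currents, rates).
    """
    currents = np.asarray(currents, dtype=float)
    n = int(round(duration / dt))
    rates = np.empty(currents.size)
    for idx, i0 in enumerate(currents):
        iapp = np.full(n, i0)
        if model == "hh":
            tr = simulate_hh(hh, resting_state(hh), iapp, dt=dt)
        elif model == "hybrid":
            if mem is None or scales is None:
                raise ValueError("hybrid F-I needs mem and scales")
            tr = simulate_hybrid(hh, mem, scales, iapp, dt=dt, law=law)
        else:
            raise ValueError(f"unknown model {model!r}")
        st = detect_spikes(tr.crop(discard), threshold=threshold, refractory=refractory)
        rates[idx] = 1000.0 * st.count / (duration - discard)
    return currents, rates
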