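"""Synthetic stimuli and device-characterization data.

Two kinds of synthetic inputs drive everything else in the package:

* the Ornstein-Uhlenbeck (OU) current noise used as the common stimulus for
  the neuron simulations (``dX = -theta X dt + sigma dW``, applied as
  ``i_app = gain * X``), and
* pulse-train device-characterization experiments emulating the published
  NbOx protocol: write-pulse potentiation with exponential decay back to a
  baseline conductance between pulses, sampled at a fixed read voltage, plus
  write-voltage sweeps.  These provide ground-truth datasets with known
  parameters for every calibration stage.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .device import MemristorParams, device_current
from .traces import TimeSeriesTrace

__all__ = [
    "OUSpec",
    "PulseProtocol",
    "ou_process",
    "pulse_voltage_waveform",
    "generate_potentiation_decay",
    "generate_pulse_sweep",
]


@dataclass(frozen=True)
class OUSpec:
    """Ornstein-Uhlenbeck stimulus specification.

    theta: mean-reversion rate (1/ms); sigma: diffusion amplitude; the
    output current is ``gain * X`` in the neuron's current-density units.
    Stationary variance of the output is ``gain^2 sigma^2 / (2 theta)``.
    """

    theta: float = 0.1   # 1/ms
    sigma: float = 0.7
    gain: float = 4.0
    dt: float = 0.005    # ms
    duration: float = 1000.0  # ms
    seed: int = 0
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


def ou_process(spec: OUSpec) -> TimeSeriesTrace:
    """Euler-Maruyama realization of the OU stimulus.

    ``X[k+1] = X[k] (1 - theta dt) + sigma sqrt(dt) xi_k``; the returned
    channel ``i_app`` is ``gain * X``.  Reproducible given the seed.
    """
    n = int(round(spec.duration / spec.dt))
    rng = np.random.default_rng(spec.seed)
    xi = rng.standard_normal(n - 1) * (spec.sigma * np.sqrt(spec.dt))
    a = 1.0 - spec.theta * spec.dt
    # X[k] = a*X[k-1] + xi[k-1]  -> linear recursion, evaluated with lfilter
    x = np.empty(n)
    x[0] = spec.x0
    x[1:] = lfilter([1.0], [1.0, -a], xi) + spec.x0 * a ** np.arange(1, n)
    t = np.arange(n) * spec.dt
    return TimeSeriesTrace(
        t=t,
        channels={"i_app": spec.gain * x},
        units={"i_app": "uA_per_cm2"},
    )


@dataclass(frozen=True)
class PulseProtocol:
    """Write/read pulse-train geometry for device characterization.

    A train of ``n_pulses`` rectangular write pulses (default 4 V, 10 ms)
    separated by ``interval`` of rest (0 V) during which the state decays;
    the conductance/current is sampled at ``read_voltage``.  The whole train
    is replicated ``replicates`` times end-to-end, mirroring the tenfold
    trace replication used to stabilize the decay-constant fit.
    """

    write_voltage: float = 4.0    # V
    write_duration: float = 10.0  # ms
    interval: float = 100.0       # ms
    read_voltage: float = 0.7     # V
    n_pulses: int = 10
    replicates: int = 10
    noise_sd: float = 0.01        # relative, multiplicative
    dt: float = 0.1               # ms

    def __post_init__(self) -> None:
        if self.write_voltage < 0 or self.read_voltage < 0:
            raise ValueError("voltages must be nonnegative")
        if self.write_duration <= 0 or self.interval <= 0 or self.dt <= 0:
            raise ValueError("durations must be positive")
        if self.n_pulses < 0 or self.replicates < 1:
            raise ValueError("need n_pulses >= 0 and replicates >= 1")


def pulse_voltage_waveform(proto: PulseProtocol, write_voltage: float | None = None,
                           replicates: int | None = None) -> TimeSeriesTrace:
    """The applied write-voltage waveform V(t) of a (replicated) pulse train."""
    vw = proto.write_voltage if write_voltage is None else float(write_voltage)
    reps = proto.replicates if replicates is None else int(replicates)
    period = proto.write_duration + proto.interval
    n_period = int(round(period / proto.dt))
    n_on = int(round(proto.write_duration / proto.dt))
    block = np.zeros(n_period * max(proto.n_pulses, 1))
    for k in range(proto.n_pulses):
        block[k * n_period : k * n_period + n_on] = vw
    V = np.tile(block, reps)
    t = np.arange(V.size) * proto.dt
    return TimeSeriesTrace(t=t, channels={"V": V}, units={"V": "volts"})


def generate_potentiation_decay(truth, proto: PulseProtocol, seed: int = 0):
    """Synthetic potentiation/decay conductance trace for the reduced-model fit.

    ``truth`` is a :class:`~memhh.calibration.ReducedModelParams`-like object
    with fields ``tau`` (ms), ``A`` (uS/ms) and ``G_min`` (uS).  Returns
    ``(G_trace, V_trace)`` where G carries optional multiplicative Gaussian
    noise of relative standard deviation ``proto.noise_sd``.
    """
    from ._kernels import reduced_model_kernel

    V = pulse_voltage_waveform(proto)
    on = np.ascontiguousarray(V["V"] > 0, dtype=float)
    G = reduced_model_kernel(on, proto.dt, float(truth.tau), float(truth.A),
                             float(truth.G_min), float(truth.G_min))
    if proto.noise_sd > 0:
        rng = np.random.default_rng(seed)
        G = G * (1.0 + proto.noise_sd * rng.standard_normal(G.size))
    G_trace = TimeSeriesTrace(t=V.t.copy(), channels={"G": G}, units={"G": "uS"})
    return G_trace, V


def generate_pulse_sweep(truth: MemristorParams, voltages, proto: PulseProtocol,
                         seed: int = 0) -> list[TimeSeriesTrace]:
    """Synthetic varying-voltage pulse experiment for the full-model fit.

    For each write voltage a single (non-replicated) pulse train is applied
    and the device current is recorded at every sample: at the write voltage
    while a pulse is on, at the read voltage otherwise.  The voltage sweep is
    what makes the tunneling slope delta and the potentiation constants
    (eta, lam) separately identifiable.  Returns one trace per write voltage
    with channels V (applied), V_meas (measurement bias), i (uA) and w.
    """
    from ._kernels import device_state_kernel

    rng = np.random.default_rng(seed)
    out = []
    for vw in voltages:
        V = pulse_voltage_waveform(proto, write_voltage=float(vw), replicates=1)
        v_arr = np.ascontiguousarray(V["V"])
        w = device_state_kernel(v_arr, proto.dt, truth.as_array(), truth.w_min)
        v_meas = np.where(v_arr > 0, v_arr, proto.read_voltage)
        i = device_current(truth, w, v_meas)
        if proto.noise_sd > 0:
            i = i * (1.0 + proto.noise_sd * rng.standard_normal(i.size))
        out.append(
            TimeSeriesTrace(
                t=V.t.copy(),
                channels={"V": v_arr, "V_meas": v_meas, "i": i, "w": w},
                units={"V": "volts", "V_meas": "volts", "i": "uA"},
            )
        )
    return out
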