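"""Spike statistics, trace-agreement scores and energy/power accounting.

Channel and circuit energies are integrals of |V_x|*|i_x| per branch (a
worst-case dissipation measure that never nets opposite-sign intervals
against each other).  Two unit conventions are supported:

``membrane`` (default)
    The integral is evaluated directly on the simulation variables: branch
    voltage ``v - E_x`` in mV, branch current density in uA/cm^2, over one
    square centimetre of membrane, in biological time (mV * uA/cm^2 * cm^2
    = nW).  This is the biological-equivalent dissipation of the emulated
    channel.

``device``
    The memristor branch is accounted in its own physical units - voltage
    ``V_scale * (v - E_K)`` volts, device current in uA - with the sodium
    and leak branches mapped by the same scaling factors
    (``i_phys = i_model / I_scale``), over physical time
    ``t_phys = T_scale * t_bio``.  This is what the scaled hardware circuit
    would dissipate; it is orders of magnitude larger than the membrane
    convention because device voltages are volts rather than millivolts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device import MemristorParams, device_current, linear_variant_current
from .hh import HHParams, gate_rates
from .hybrid import ScalingFactors
from .traces import TimeSeriesTrace

__all__ = [
    "SpikeTrain",
    "detect_spikes",
    "spike_height_reduction",
    "spike_coincidence",
    "EnergyReport",
    "channel_energy",
    "circuit_energy",
    "energy_report",
    "brain_extrapolation",
    "mse_score",
    "r2_score",
]


@dataclass
class SpikeTrain:
    """Detected spikes: times (ms), per-spike peak voltages (mV), and the
    detection settings that produced them."""

    times: np.ndarray
    peaks: np.ndarray
    threshold: float
    refractory: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.times.size and np.any(np.diff(self.times) < self.refractory - 1e-9):
            raise ValueError("spike times violate the refractory gap")

    @property
    def count(self) -> int:
        return int(self.times.size)

    def rate(self, duration_ms: float) -> float:
        """Mean firing rate in Hz over the given biological duration."""
        return 1000.0 * self.count / duration_ms


def detect_spikes(trace: TimeSeriesTrace | np.ndarray, threshold: float = -30.0,
                  refractory: float = 2.0, dt: float | None = None,
                  channel: str = "V") -> SpikeTrain:
    """Upward threshold crossings with refractory suppression.

    Each spike's peak is the maximum voltage between the upward and the next
    downward crossing.  The default -30 mV threshold catches both full-height
    HH spikes and the ~40%-reduced hybrid spikes.
    """
    if isinstance(trace, TimeSeriesTrace):
        V = np.asarray(trace[channel], dtype=float)
        dt = trace.dt
    else:
        V = np.asarray(trace, dtype=float)
        if dt is None:
            raise ValueError("dt is required when passing a bare array")
    above = V >= threshold
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, peaks = [], []
    last = -np.inf
    for k in ups:
        t_k = k * dt
        if t_k - last < refractory:
            continue
        end = k
        while end < V.size and V[end] >= threshold:
            end += 1
        times.append(t_k)
        peaks.append(V[k:end].max())
        last = t_k
    return SpikeTrain(np.array(times), np.array(peaks), threshold, refractory)


def spike_height_reduction(reference: TimeSeriesTrace, test: TimeSeriesTrace,
                           threshold: float = -30.0, refractory: float = 2.0,
                           baseline: tuple[float, float] | None = None) -> float:
    """Fractional loss of mean spike height in ``test`` relative to ``reference``.

    Heights are measured above each trace's own resting baseline (the mean
    voltage over ``baseline`` = (t0, t1) ms, defaulting to the first 5 ms,
    before stimulation has moved the membrane).  Returns
    ``1 - mean_height_test / mean_height_ref``; 0 for identical traces,
    positive when the test spikes are smaller.
    """
    t0, t1 = baseline if baseline is not None else (0.0, 5.0)

    def mean_height(tr: TimeSeriesTrace) -> float:
        st = detect_spikes(tr, threshold=threshold, refractory=refractory)
        if st.count == 0:
            raise ValueError("no spikes detected in trace")
        base = float(np.mean(tr.crop(t0, t1)["V"]))
        return float(np.mean(st.peaks) - base)

    return 1.0 - mean_height(test) / mean_height(reference)


def spike_coincidence(reference: SpikeTrain, test: SpikeTrain,
                      window: float = 5.0) -> float:
    """Fraction of reference spikes with a test spike within +-window ms."""
    if reference.count == 0:
        raise ValueError("reference train is empty")
    if test.count == 0:
        return 0.0
    hits = 0
    for t in reference.times:
        if np.min(np.abs(test.times - t)) <= window:
            hits += 1
    return hits / reference.count


# ---------------------------------------------------------------------------
# Energy accounting


@dataclass
class EnergyReport:
    """Energy/power bookkeeping for one hybrid simulation interval.

    Headline fields use the ``membrane`` convention (biological-equivalent
    units, biological time); the ``*_device`` fields restate the energies in
    physical device units over physical time (see the module docstring).
    Mean powers are the energies divided by the accounted duration of their
    own time base.
    """

    E_K: float                  # J, membrane convention
    E_HH: float                 # J, membrane convention
    E_K_device: float           # J, device convention (physical time)
    E_HH_device: float          # J, device convention
    duration_bio_s: float       # s of biological time accounted
    duration_phys_s: float      # s of physical time accounted
    mean_power_K: float         # W, membrane convention
    mean_power_HH: float        # W, membrane convention
    spike_count: int
    energy_per_spike_K: float   # J: mean_power_K * duration_bio / spikes
    energy_per_spike_HH: float  # J

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _element_powers(trace: TimeSeriesTrace, hh: HHParams, mem: MemristorParams,
                    scales: ScalingFactors, law: str = "sinh",
                    convention: str = "membrane") -> dict[str, np.ndarray]:
    """Instantaneous |V|*|i| per circuit element along a hybrid trace.

    Units: uW in the ``device`` convention, nW (per cm^2 of membrane) in the
    ``membrane`` convention.
    """
    v = np.asarray(trace["V"], dtype=float)
    w = np.asarray(trace["w"], dtype=float)
    m = np.asarray(trace["m"], dtype=float)
    h = np.asarray(trace["h"], dtype=float)
    fn = device_current if law == "sinh" else linear_variant_current
    i_k_model = scales.I_scale * fn(mem, np.clip(w, mem.w_min, mem.w_max),
                                    scales.V_scale * (v - hh.E_K))  # uA/cm^2
    i_na_model = hh.g_Na * m**3 * h * (v - hh.E_Na)
    i_l_model = hh.g_L * (v - hh.E_L)
    if convention == "membrane":
        return {
            "K": np.abs(v - hh.E_K) * np.abs(i_k_model),
            "Na": np.abs(v - hh.E_Na) * np.abs(i_na_model),
            "L": np.abs(v - hh.E_L) * np.abs(i_l_model),
        }
    if convention == "device":
        return {
            "K": np.abs(scales.V_scale * (v - hh.E_K)) * np.abs(i_k_model / scales.I_scale),
            "Na": np.abs(scales.V_scale * (v - hh.E_Na)) * np.abs(i_na_model / scales.I_scale),
            "L": np.abs(scales.V_scale * (v - hh.E_L)) * np.abs(i_l_model / scales.I_scale),
        }
    raise ValueError(f"unknown energy convention {convention!r}")


def _energy(trace, hh, mem, scales, t1, t2, law, convention, elements):
    sub = trace.crop(t1, t2)
    powers = _element_powers(sub, hh, mem, scales, law=law, convention=convention)
    total = sum(powers[e] for e in elements)
    if convention == "membrane":
        dt_ms = sub.dt            # biological time; power in nW
        to_joule = 1e-12          # nW * ms
    else:
        dt_ms = sub.dt * scales.T_scale  # physical time; power in uW
        to_joule = 1e-9           # uW * ms
    return float(np.trapezoid(total, dx=dt_ms) * to_joule)


def channel_energy(trace: TimeSeriesTrace, hh: HHParams, mem: MemristorParams,
                   scales: ScalingFactors, t1: float = 0.0, t2: float | None = None,
                   law: str = "sinh", convention: str = "membrane") -> float:
    """Energy (J) dissipated in the memristor K branch over [t1, t2] (bio ms)."""
    return _energy(trace, hh, mem, scales, t1, t2, law, convention, ("K",))


def circuit_energy(trace: TimeSeriesTrace, hh: HHParams, mem: MemristorParams,
                   scales: ScalingFactors, t1: float = 0.0, t2: float | None = None,
                   law: str = "sinh", convention: str = "membrane") -> float:
    """Energy (J) over [t1, t2] summed over the K, Na and leak branches."""
    return _energy(trace, hh, mem, scales, t1, t2, law, convention, ("K", "Na", "L"))


def energy_report(trace: TimeSeriesTrace, hh: HHParams, mem: MemristorParams,
                  scales: ScalingFactors, t1: float = 0.0, t2: float | None = None,
                  law: str = "sinh", threshold: float = -30.0,
                  refractory: float = 2.0) -> EnergyReport:
    """Full energy/power/spike bookkeeping over [t1, t2] (biological ms)."""
    sub = trace.crop(t1, t2)
    dur_bio_s = sub.duration * 1e-3
    dur_phys_s = dur_bio_s * scales.T_scale
    e_k = channel_energy(trace, hh, mem, scales, t1, t2, law=law)
    e_hh = circuit_energy(trace, hh, mem, scales, t1, t2, law=law)
    spikes = detect_spikes(sub, threshold=threshold, refractory=refractory)
    p_k = e_k / dur_bio_s
    p_hh = e_hh / dur_bio_s
    n = max(spikes.count, 1)
    return EnergyReport(
        E_K=e_k,
        E_HH=e_hh,
        E_K_device=channel_energy(trace, hh, mem, scales, t1, t2, law=law,
                                  convention="device"),
        E_HH_device=circuit_energy(trace, hh, mem, scales, t1, t2, law=law,
                                   convention="device"),
        duration_bio_s=dur_bio_s,
        duration_phys_s=dur_phys_s,
        mean_power_K=p_k,
        mean_power_HH=p_hh,
        spike_count=spikes.count,
        energy_per_spike_K=p_k * dur_bio_s / n,
        energy_per_spike_HH=p_hh * dur_bio_s / n,
    )


def brain_extrapolation(power_per_neuron: float, n_neurons: float = 8.6e10) -> float:
    """Whole-brain power (kW) if every neuron dissipated ``power_per_neuron`` (W)."""
    if power_per_neuron < 0:
        raise ValueError("power must be nonnegative")
    return power_per_neuron * n_neurons * 1e-3


# ---------------------------------------------------------------------------
# Trace agreement


def _aligned(a, b, discard: float, dt: float | None):
    if isinstance(a, TimeSeriesTrace):
        dt = a.dt
        a = a["V"] if "V" in a else next(iter(a.channels.values()))
    if isinstance(b, TimeSeriesTrace):
        b = b["V"] if "V" in b else next(iter(b.channels.values()))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must be sampled identically")
    if discard > 0:
        if dt is None:
            raise ValueError("dt required to discard an initial transient from arrays")
        k = int(round(discard / dt))
        a, b = a[k:], b[k:]
    return a, b


def mse_score(a, b, discard: float = 25.0, dt: float | None = None) -> float:
    """Mean squared error after discarding the initial transient (ms)."""
    x, y = _aligned(a, b, discard, dt)
    return float(np.mean((x - y) ** 2))


def r2_score(a, b, discard: float = 0.0, dt: float | None = None) -> float:
    """Coefficient of determination of ``b`` against truth ``a``; 1 for a
    perfect match, <= 0 for a predictor no better than the mean."""
    x, y = _aligned(a, b, discard, dt)
    ss_res = np.sum((x - y) ** 2)
    ss_tot = np.sum((x - np.mean(x)) ** 2)
    return float(1.0 - ss_res / ss_tot)
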