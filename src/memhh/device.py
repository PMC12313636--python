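"""Volatile oxygen-vacancy memristor device law.

The device is a two-terminal element whose conductance is controlled by a
dimensionless internal state ``w`` (the filament / vacancy-concentration
coordinate).  Conduction is the parallel combination of a modulated Schottky
barrier and interfacial tunneling::

    i(w, V) = (1 - w) * alpha * (1 - exp(-beta * V)) + w * gamma * sinh(delta * V)

with ``i`` in microamperes for ``V`` in volts.  The state potentiates under
bias and decays toward its baseline when unbiased (volatility)::

    dw/dt = W(w) * lam * sinh(eta * V) - (w - w_min) / tau

where the window ``W(w) = 1 - exp(w - 3)`` throttles potentiation as the
state grows; it multiplies the potentiation term only.  ``w`` is confined to
``[w_min, w_max]`` by clipping after every forward-Euler step.

Two calibrated presets ship with the package: ``"nbox"`` (NbOx, decay
``tau = 11.7 ms``) and ``"wox"`` (WOx, ``tau = 50 ms``).  A hypothetical
linear-conductance variant (the small-signal expansion promoted to a device
law) is provided for comparison studies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .traces import TimeSeriesTrace

__all__ = [
    "MemristorParams",
    "device_current",
    "window",
    "state_rate",
    "step_state",
    "steady_state_w",
    "effective_time_constant",
    "linearized_current",
    "linear_variant_current",
    "simulate_device",
    "hysteresis_trace",
    "SINH_ARG_LIMIT",
]

logger = logging.getLogger(__name__)

#: |eta*V| and |delta*V| are clamped to this value before exponentiation;
#: larger arguments are unphysical for these devices and would overflow.
SINH_ARG_LIMIT = 40.0


@dataclass(frozen=True)
class MemristorParams:
    """Constants of the volatile memristor law.

    tau : decay time constant (ms)
    alpha : Schottky current scale (uA)
    beta : Schottky voltage slope (1/V)
    gamma : tunneling current scale (uA)
    delta : tunneling voltage slope (1/V)
    eta : potentiation voltage slope (1/V)
    lam : potentiation rate scale (1/ms)
    w_min, w_max : state bounds (dimensionless)
    """

    tau: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    eta: float
    lam: float
    w_min: float
    w_max: float = 0.99

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        for name in ("alpha", "beta", "gamma", "delta", "eta", "lam"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.w_min < self.w_max <= 1):
            raise ValueError("state bounds must satisfy 0 < w_min < w_max <= 1")

    # fixed ordering used by the numba kernels
    _ORDER = ("tau", "alpha", "beta", "gamma", "delta", "eta", "lam", "w_min", "w_max")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self._ORDER], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self._ORDER}

    def with_tau(self, tau: float) -> "MemristorParams":
        """Copy with a modified decay constant (used for the WOx speed-up study)."""
        return replace(self, tau=tau)

    @classmethod
    def from_dict(cls, d: dict) -> "MemristorParams":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_json(cls, path) -> "MemristorParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def preset(cls, name: str) -> "MemristorParams":
        """Load a shipped device preset: ``"nbox"`` or ``"wox"``."""
        name = name.lower()
        if name not in ("nbox", "wox"):
            raise KeyError(f"unknown device preset {name!r}; available: nbox, wox")
        text = resources.files("memhh.presets").joinpath(f"{name}.json").read_text()
        return cls.from_dict(json.loads(text))


def _check_w(p: MemristorParams, w) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if np.any(w < p.w_min - 1e-12) or np.any(w > p.w_max + 1e-12):
        raise ValueError(
            f"state w out of bounds [{p.w_min}, {p.w_max}]: "
            f"range [{w.min():.6g}, {w.max():.6g}]"
        )
    return w


def _clamped(x: np.ndarray) -> np.ndarray:
    if np.any(np.abs(x) > SINH_ARG_LIMIT):
        logger.warning("voltage argument clamped to |x| <= %.0f before exponentiation", SINH_ARG_LIMIT)
        x = np.clip(x, -SINH_ARG_LIMIT, SINH_ARG_LIMIT)
    return x


def device_current(p: MemristorParams, w, V):
    """Device current (uA) at state ``w`` and applied voltage ``V`` (volts).

    Sum of the Schottky term ``(1-w)*alpha*(1-exp(-beta*V))`` and the
    tunneling term ``w*gamma*sinh(delta*V)``; both vanish at V = 0 (pinched
    hysteresis) and carry the sign of V.
    """
    w = _check_w(p, w)
    V = np.asarray(V, dtype=float)
    schottky = (1.0 - w) * p.alpha * (1.0 - np.exp(-_clamped(p.beta * V)))
    tunnel = w * p.gamma * np.sinh(_clamped(p.delta * V))
    out = schottky + tunnel
    return float(out) if out.ndim == 0 else out


def window(p: MemristorParams, w):
    """Potentiation window ``W(w) = 1 - exp(w - 3)``, strictly decreasing in w."""
    w = np.asarray(w, dtype=float)
    out = 1.0 - np.exp(w - 3.0)
    return float(out) if out.ndim == 0 else out


def state_rate(p: MemristorParams, w, V):
    """dw/dt (1/ms): windowed potentiation minus first-order decay to w_min."""
    w = _check_w(p, w)
    V = np.asarray(V, dtype=float)
    pot = window(p, w) * p.lam * np.sinh(_clamped(p.eta * V))
    out = pot - (w - p.w_min) / p.tau
    return float(out) if np.ndim(out) == 0 else out


def step_state(p: MemristorParams, w, V, dt: float):
    """One forward-Euler update of the state, clipped to [w_min, w_max]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = np.clip(np.asarray(w, float) + dt * state_rate(p, w, V), p.w_min, p.w_max)
    return float(out) if np.ndim(out) == 0 else out


def steady_state_w(p: MemristorParams, V):
    """Steady state of ``w`` at constant bias, ignoring the window.

    ``w_inf = clip(w_min + tau * lam * sinh(eta * V), w_min, w_max)``:
    ``w_min`` at V = 0, saturating at ``w_max`` for
    ``V >= asinh(w_max / (tau * lam)) / eta``.  Non-decreasing in V >= 0,
    the sigmoid-like activation that mirrors the potassium n-gate.
    """
    V = np.asarray(V, dtype=float)
    out = np.clip(p.w_min + p.tau * p.lam * np.sinh(_clamped(p.eta * V)), p.w_min, p.w_max)
    return float(out) if out.ndim == 0 else out


def effective_time_constant(p: MemristorParams, V) -> float:
    """Dominant relaxation time (ms) of ``w`` near its baseline at bias V >= 0.

    For weak drive (``tau * lam * sinh(eta V) < 1``) decay dominates and the
    time constant is ``tau``; for strong drive it is set by potentiation,
    ``1 / (lam * sinh(eta V))``, which is then necessarily shorter than tau.
    """
    V = float(V)
    if V < 0:
        raise ValueError("effective_time_constant defined for V >= 0")
    drive = p.tau * p.lam * math.sinh(min(p.eta * V, SINH_ARG_LIMIT))
    if drive < 1.0:
        return p.tau
    return 1.0 / (p.lam * math.sinh(min(p.eta * V, SINH_ARG_LIMIT)))


def linearized_current(p: MemristorParams, w, V):
    """Small-signal expansion of the device law around V = 0.

    ``i ~ w * (gamma*delta - alpha*beta) * V + alpha*beta * V``: a
    state-proportional conductance plus a persistent Schottky leak
    ``alpha*beta``; the residual against the full law is O(V^2).
    """
    w = np.asarray(w, dtype=float)
    V = np.asarray(V, dtype=float)
    out = w * (p.gamma * p.delta - p.alpha * p.beta) * V + p.alpha * p.beta * V
    return float(out) if out.ndim == 0 else out


def linear_variant_current(p: MemristorParams, w, V):
    """Hypothetical linear-conductance device: the expansion used as the law.

    Conductance ``i / V`` is independent of V at fixed w, removing the sinh
    surge that limits spike height in the hybrid neuron.
    """
    return linearized_current(p, w, V)


def simulate_device(p: MemristorParams, V: np.ndarray, dt: float, w0: float | None = None,
                    law: str = "sinh") -> TimeSeriesTrace:
    """Integrate the state equation under an applied voltage waveform.

    Parameters
    ----------
    V
        Applied voltage samples (volts) at spacing ``dt`` (ms).
    w0
        Initial state; defaults to ``w_min``.
    law
        ``"sinh"`` for the full device law or ``"linear"`` for the
        linear-conductance variant (state dynamics are shared).
    """
    from ._kernels import device_state_kernel

    if dt <= 0:
        raise ValueError("dt must be positive")
    V = np.ascontiguousarray(V, dtype=float)
    w0 = p.w_min if w0 is None else float(w0)
    w = device_state_kernel(V, dt, p.as_array(), w0)
    if law == "sinh":
        i = device_current(p, w, V)
    elif law == "linear":
        i = linear_variant_current(p, w, V)
    else:
        raise ValueError(f"unknown law {law!r}")
    t = np.arange(V.size) * dt
    return TimeSeriesTrace(
        t=t,
        channels={"V": V, "i": i, "w": w},
        units={"V": "volts", "i": "uA"},
    )


def hysteresis_trace(p: MemristorParams, amplitude: float, freq: float, dt: float,
                     cycles: int = 1, w0: float | None = None) -> TimeSeriesTrace:
    """I-V trajectory under sinusoidal drive ``V(t) = amplitude*sin(2*pi*f*t)``.

    ``freq`` in kHz (cycles per ms).  The loop is pinched: i = 0 whenever
    V = 0, for any state.
    """
    n = max(2, int(round(cycles / (freq * dt))))
    t = np.arange(n) * dt
    V = amplitude * np.sin(2 * np.pi * freq * t)
    return simulate_device(p, V, dt, w0=w0)
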