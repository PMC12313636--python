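"""Uniformly sampled multichannel time series.

All simulators in this package exchange data through :class:`TimeSeriesTrace`:
a time axis in milliseconds plus named channels (voltage, current, gating or
device state...), with an optional unit tag per channel.  CSV round-tripping
goes through pandas so traces interoperate with ordinary dataframe tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeriesTrace"]


@dataclass
class TimeSeriesTrace:
    """A uniformly sampled signal with named channels.

    Parameters
    ----------
    t
        Sample times in milliseconds, uniformly spaced.
    channels
        Mapping from channel name to a 1-D (or, for multi-compartment
        voltage matrices, 2-D ``(n_samples, n_columns)``) array aligned
        with ``t``.
    units
        Optional per-channel unit tags (e.g. ``{"V": "mV"}``).
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("t must be a 1-D array with at least two samples")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("t must be uniformly spaced")
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != self.t.size:
                raise ValueError(f"channel {name!r} length {arr.shape[0]} != {self.t.size}")
            self.channels[name] = arr

    @property
    def dt(self) -> float:
        """Sampling interval in ms."""
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Span from first to last sample in ms."""
        return float(self.t[-1] - self.t[0])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def crop(self, t_start: float = 0.0, t_stop: float | None = None) -> "TimeSeriesTrace":
        """Return the sub-trace with t_start <= t <= t_stop (ms)."""
        mask = self.t >= t_start
        if t_stop is not None:
            mask &= self.t <= t_stop
        return TimeSeriesTrace(
            t=self.t[mask],
            channels={k: v[mask] for k, v in self.channels.items()},
            units=dict(self.units),
        )

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t_ms": self.t}
        for name, arr in self.channels.items():
            if arr.ndim == 1:
                cols[self._header(name)] = arr
            else:
                for j in range(arr.shape[1]):
                    cols[f"{self._header(name)}_{j}"] = arr[:, j]
        return pd.DataFrame(cols)

    def _header(self, name: str) -> str:
        unit = self.units.get(name)
        return f"{name}_{unit}" if unit else name

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesTrace":
        df = pd.read_csv(path)
        if "t_ms" not in df.columns:
            raise ValueError("trace CSV must have a t_ms column")
        channels: dict[str, np.ndarray] = {}
        units: dict[str, str] = {}
        known_units = ("mV", "volts", "uA", "uS", "uA_per_cm2")
        for col in df.columns:
            if col == "t_ms":
                continue
            name, unit = col, None
            for u in known_units:
                if col.endswith("_" + u):
                    name, unit = col[: -len(u) - 1], u
                    break
            channels[name] = df[col].to_numpy()
            if unit:
                units[name] = unit
        return cls(t=df["t_ms"].to_numpy(), channels=channels, units=units)
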