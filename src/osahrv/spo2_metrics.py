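"""Overnight pulse-oximetry summary indices.

Two indices enter the severity models: the minimum saturation reached during
sleep (SatMin) and the percentage of sleep time spent below 90% saturation
(T90).  Total sleep time is taken as the trace duration; no hypnogram is
used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SpO2Trace", "sat_min", "t90"]


@dataclass
class SpO2Trace:
    """A uniformly sampled oxygen-saturation time series for one night.

    sat : saturation values in %, one per sample.
    sample_hz : sampling rate, Hz (>= 0.5 Hz for meaningful T90).
    t_start : offset of the first sample from sleep onset, seconds.
    """

    sat: np.ndarray
    sample_hz: float = 1.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.sat = np.asarray(self.sat, dtype=float)
        if self.sat.ndim != 1:
            raise ValueError("sat must be one-dimensional")
        if self.sample_hz <= 0:
            raise ValueError("sample_hz must be positive")
        if len(self.sat) and (self.sat.min() < 0 or self.sat.max() > 100):
            raise ValueError("saturation values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.sat)

    @property
    def t(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.sat)) / self.sample_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "sat": self.sat})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpO2Trace":
        t = df["t"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("trace needs at least two samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        return cls(sat=df["sat"].to_numpy(dtype=float), sample_hz=1.0 / dt[0], t_start=t[0])


def sat_min(trace: SpO2Trace) -> float:
    """Minimum oxygen saturation over total sleep time, %."""
    if len(trace) == 0:
        raise ValueError("empty SpO2 trace")
    return float(trace.sat.min())


def t90(trace: SpO2Trace) -> float:
    """Percentage of total sleep time with saturation strictly below 90%."""
    if len(trace) == 0:
        raise ValueError("empty SpO2 trace")
    return float(100.0 * np.mean(trace.sat < 90.0))
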