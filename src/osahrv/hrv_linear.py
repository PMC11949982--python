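"""Time-domain statistics and spectral band powers of an RR-interval series.

The tachogram is resampled to an evenly spaced signal at 3 Hz by cubic-spline
interpolation on the cumulative-time axis, and the spectrum is estimated by
averaged 512-sample periodograms (50% overlap, Hann window with power
compensation, per-window mean removal) — i.e. Welch's method.  Band powers
integrate the averaged spectrum over the very-low (VLF), low (LF) and high
(HF) frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .rri_preprocess import RRiSeries

__all__ = ["SpectralConfig", "time_domain", "spectral", "LINEAR_COLUMNS"]

LINEAR_COLUMNS = [
    "MeanRR", "SDNN", "RMSSD",
    "VLFabs", "LFabs", "HFabs", "LFnu", "HFnu", "LF/HF",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the Welch band-power estimate.

    resample_hz : even-sampling rate of the interpolated tachogram, Hz.
    segment_len : periodogram segment length, samples.
    overlap : fractional overlap between consecutive segments.
    vlf_lo : lower VLF integration bound, Hz (the upper VLF edge is the
        lower LF edge).
    """

    resample_hz: float = 3.0
    segment_len: int = 512
    overlap: float = 0.5
    vlf_lo: float = 0.003
    vlf_hi: float = 0.04
    lf_hi: float = 0.15
    hf_hi: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        edges = (self.vlf_lo, self.vlf_hi, self.lf_hi, self.hf_hi)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")


def time_domain(series: RRiSeries) -> dict[str, float]:
    """MeanRR (ms), SDNN (ms, sample SD), RMSSD (ms)."""
    x = series.values
    if len(x) < 2:
        raise ValueError("time-domain indices need at least 2 beats")
    return {
        "MeanRR": float(x.mean()),
        "SDNN": float(x.std(ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(np.diff(x) ** 2))),
    }


def resample_tachogram(series: RRiSeries, fs: float = 3.0) -> np.ndarray:
    """Evenly sampled RR signal: cubic spline of RR value against beat time."""
    t = np.cumsum(series.values) / 1000.0
    if len(t) < 4:
        raise ValueError("too few beats for cubic-spline resampling")
    spline = CubicSpline(t, series.values)
    grid = np.arange(t[0], t[-1], 1.0 / fs)
    return spline(grid)


def spectral(
    series: RRiSeries | np.ndarray,
    cfg: SpectralConfig = SpectralConfig(),
    *,
    resampled: bool = False,
) -> dict[str, float]:
    """Band powers (ms^2), normalized units (%) and the LF/HF ratio.

    ``series`` may be an :class:`RRiSeries` (resampled internally) or, with
    ``resampled=True``, an already evenly sampled signal at ``cfg.resample_hz``.
    ``LF/HF`` is NaN when the HF power is zero.
    """
    if resampled:
        x = np.asarray(series, dtype=float)
    else:
        x = resample_tachogram(series, cfg.resample_hz)
    if len(x) < cfg.segment_len:
        raise ValueError(
            f"resampled signal of {len(x)} samples is shorter than one "
            f"{cfg.segment_len}-sample spectral segment"
        )
    freqs, psd = signal.welch(
        x,
        fs=cfg.resample_hz,
        window="hann",
        nperseg=cfg.segment_len,
        noverlap=int(cfg.segment_len * cfg.overlap),
        detrend="constant",
        scaling="density",
    )
    df = freqs[1] - freqs[0]

    def band(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs < hi)
        return float(psd[sel].sum() * df)

    vlf = band(cfg.vlf_lo, cfg.vlf_hi)
    lf = band(cfg.vlf_hi, cfg.lf_hi)
    hf = band(cfg.lf_hi, cfg.hf_hi)
    denom = lf + hf
    lfnu = 100.0 * lf / denom if denom > 0 else np.nan
    hfnu = 100.0 * hf / denom if denom > 0 else np.nan
    lf_hf = lf / hf if hf > 0 else np.nan
    return {
        "VLFabs": vlf, "LFabs": lf, "HFabs": hf,
        "LFnu": lfnu, "HFnu": hfnu, "LF/HF": lf_hf,
    }


def total_power(x: np.ndarray, cfg: SpectralConfig = SpectralConfig()) -> float:
    """Integrated power of the averaged periodogram over all frequencies.

    With the Hann power compensation built into the Welch estimate, this
    matches the signal variance for stationary input (Parseval check).
    """
    freqs, psd = signal.welch(
        np.asarray(x, dtype=float),
        fs=cfg.resample_hz,
        window="hann",
        nperseg=cfg.segment_len,
        noverlap=int(cfg.segment_len * cfg.overlap),
        detrend="constant",
        scaling="density",
    )
    return float(np.trapezoid(psd, freqs))
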