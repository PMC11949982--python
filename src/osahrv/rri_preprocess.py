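"""Spurious-beat correction and hourly segment selection for RR-interval series.

The cleaning stage estimates a baseline with a centered moving median and
replaces beats falling outside a tolerance band around that baseline by
linear interpolation.  A series needing more than ``max_corrected_frac``
replacements (default 2.5%) is flagged ineligible for downstream analysis.
From each recording hour, one contiguous 15-minute window is selected by an
automated quality score: the fraction of out-of-band beats, evaluated before
any correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RRiSeries",
    "CorrectionParams",
    "IneligibleSeriesError",
    "InsufficientDataError",
    "correct_rri",
    "select_segments",
]


class IneligibleSeriesError(ValueError):
    """Raised when a series exceeds the allowed fraction of corrected beats."""


class InsufficientDataError(ValueError):
    """Raised when a recording does not cover the required duration."""


@dataclass
class RRiSeries:
    """An ordered beat-to-beat RR-interval series in milliseconds.

    Parameters
    ----------
    values : ndarray
        RR intervals, ms, all positive.
    t_start : float
        Offset of the first beat from sleep onset, seconds.
    corrected_mask : ndarray of bool, optional
        Per-beat flag marking interpolated (corrected) beats.
    """

    values: np.ndarray
    t_start: float = 0.0
    corrected_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("RRi values must be one-dimensional")
        if len(self.values) and np.any(self.values <= 0):
            raise ValueError("RR intervals must be positive")
        if self.corrected_mask is None:
            self.corrected_mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.corrected_mask = np.asarray(self.corrected_mask, dtype=bool)
            if self.corrected_mask.shape != self.values.shape:
                raise ValueError("corrected_mask must match values in length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_corrected(self) -> int:
        return int(self.corrected_mask.sum())

    @property
    def duration_s(self) -> float:
        """Total time spanned by the beats, seconds."""
        return float(self.values.sum() / 1000.0)

    def beat_times(self) -> np.ndarray:
        """Cumulative beat times in seconds from ``t_start`` (end of each beat)."""
        return self.t_start + np.cumsum(self.values) / 1000.0


@dataclass(frozen=True)
class CorrectionParams:
    """Moving-median band parameters for spurious-beat correction.

    window_W : odd number of beats in the centered moving-median window.
    tolerance_T : half-width of the tolerance band as a fraction of the
        baseline average.
    max_corrected_frac : maximum tolerated fraction of replaced beats.
    """

    window_W: int = 11
    tolerance_T: float = 0.2
    max_corrected_frac: float = 0.025

    def __post_init__(self) -> None:
        if self.window_W < 3 or self.window_W % 2 == 0:
            raise ValueError("window_W must be odd and >= 3")
        if not 0.0 < self.tolerance_T < 1.0:
            raise ValueError("tolerance_T must lie in (0, 1)")
        if not 0.0 < self.max_corrected_frac <= 1.0:
            raise ValueError("max_corrected_frac must lie in (0, 1]")


def _moving_median(values: np.ndarray, window: int) -> np.ndarray:
    # Centered window; shrinks near the edges so the output keeps full length.
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def _out_of_band(values: np.ndarray, params: CorrectionParams) -> np.ndarray:
    baseline = _moving_median(values, params.window_W)
    half_width = params.tolerance_T * baseline.mean()
    return (values > baseline + half_width) | (values < baseline - half_width)


def correct_rri(
    series: RRiSeries,
    params: CorrectionParams = CorrectionParams(),
    *,
    raise_if_ineligible: bool = True,
) -> RRiSeries:
    """Replace out-of-band beats by linear interpolation between in-band neighbors.

    The baseline is a centered moving median of width ``window_W``; the
    tolerance band extends ``tolerance_T`` times the mean baseline above and
    below it.  Runs of consecutive out-of-band beats are replaced as a block,
    anchored on the nearest in-band beat on each side (the nearest in-band
    value is held constant when a run touches a series edge).

    Raises
    ------
    InsufficientDataError
        If the series is shorter than the median window.
    IneligibleSeriesError
        If more than ``max_corrected_frac`` of beats require replacement and
        ``raise_if_ineligible`` is true.
    """
    n = len(series)
    if n < params.window_W:
        raise InsufficientDataError(
            f"series of {n} beats is shorter than the W={params.window_W} window"
        )
    bad = _out_of_band(series.values, params)
    frac = bad.mean()
    if frac > params.max_corrected_frac and raise_if_ineligible:
        raise IneligibleSeriesError(
            f"{frac:.1%} of beats out of band exceeds the "
            f"{params.max_corrected_frac:.1%} eligibility bound"
        )
    corrected = series.values.copy()
    if bad.any():
        if bad.all():
            raise IneligibleSeriesError("no in-band beats to anchor interpolation")
        idx = np.arange(n)
        corrected[bad] = np.interp(idx[bad], idx[~bad], corrected[~bad])
    return RRiSeries(
        values=corrected,
        t_start=series.t_start,
        corrected_mask=series.corrected_mask | bad,
    )


def quality_score(values: np.ndarray, params: CorrectionParams = CorrectionParams()) -> float:
    """Automated segment quality: fraction of out-of-band beats before correction."""
    if len(values) < params.window_W:
        return 1.0
    return float(_out_of_band(np.asarray(values, dtype=float), params).mean())


def select_segments(
    series_per_hour: list[RRiSeries],
    duration: float = 900.0,
    n_hours: int = 6,
    step: float = 60.0,
    params: CorrectionParams = CorrectionParams(),
) -> list[RRiSeries]:
    """Pick the best contiguous ``duration``-second window from each hour.

    Candidate windows start every ``step`` seconds within the hour and never
    cross hour boundaries.  The window minimizing the out-of-band beat
    fraction wins; ties go to the earliest offset.

    Raises
    ------
    InsufficientDataError
        If fewer than ``n_hours`` hourly series are available or any hour
        holds less than ``duration`` seconds of beats.
    """
    if len(series_per_hour) < n_hours:
        raise InsufficientDataError(
            f"{len(series_per_hour)} hours available, {n_hours} required"
        )
    segments: list[RRiSeries] = []
    for hour_idx, hour in enumerate(series_per_hour[:n_hours]):
        total = hour.duration_s
        if total < duration:
            raise InsufficientDataError(
                f"hour {hour_idx} spans {total:.0f} s < required {duration:.0f} s"
            )
        ends = np.cumsum(hour.values) / 1000.0  # end time of each beat, s
        starts = ends - hour.values / 1000.0
        best: tuple[float, float, np.ndarray] | None = None
        offset = 0.0
        while offset + duration <= total + 1e-9:
            in_win = (starts >= offset - 1e-9) & (ends <= offset + duration + 1e-9)
            vals = hour.values[in_win]
            score = quality_score(vals, params)
            if best is None or score < best[0] - 1e-12:
                best = (score, offset, vals)
            offset += step
        assert best is not None
        score, offset, vals = best
        segments.append(RRiSeries(values=vals, t_start=hour.t_start + offset))
    return segments
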