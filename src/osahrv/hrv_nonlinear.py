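"""Nonlinear HRV indices.

Twenty-five indices covering six families:

* fractal scaling — short-range detrended fluctuation exponent (DFA alpha-1);
* irregularity — sample, fuzzy, dispersion, phase, distribution, permutation
  and attention entropies;
* coarse-grained symbolic dynamics — the Max-Min scheme (six amplitude bins,
  3-symbol words: 0V/1V/2LV/2UV) and the binary scheme (sign of successive
  differences, words by number of symbol changes: 0V/1V/2V);
* heart-rate fragmentation — percentage of inflection points (PIP) and
  4-symbol word percentages W0-W3;
* time-irreversibility (asymmetry) — Porta's, Guzik's and Ehlers' indices;
* phase-rectified signal averaging — acceleration and deceleration capacity
  (AC/DC).

All estimators operate on a plain 1-D array of RR intervals (ms).  Functions
return ``nan`` for inputs on which the index is undefined (e.g. a constant
series for range-based symbolizations), so that a feature table can carry
the gap explicitly instead of failing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import norm

__all__ = [
    "EntropyParams",
    "PRSAParams",
    "dfa_alpha1",
    "sample_entropy",
    "fuzzy_entropy",
    "dispersion_entropy",
    "permutation_entropy",
    "phase_entropy",
    "distribution_entropy",
    "attention_entropy",
    "symbolic_maxmin",
    "symbolic_binary",
    "fragmentation",
    "asymmetry",
    "prsa_acdc",
    "nonlinear_indices",
    "NONLINEAR_COLUMNS",
]

NONLINEAR_COLUMNS = [
    "DFA-a1",
    "SampEn", "FuzzyEn", "DispEn", "PhaseEn", "DistEn", "PermEn", "AttEn",
    "Symb-0V", "Symb-1V", "Symb-2LV", "Symb-2UV",
    "Bin-0V", "Bin-1V", "Bin-2V",
    "HRF-PIP", "HRF-W0", "HRF-W1", "HRF-W2", "HRF-W3",
    "Porta", "Guzik", "Ehlers",
    "AC", "DC",
]


@dataclass(frozen=True)
class EntropyParams:
    """Per-estimator parameters of the entropy family.

    Tolerances ``r`` are expressed as a fraction of the series SD.
    """

    sampen_m: int = 2
    sampen_r: float = 0.15
    fuzzy_m: int = 2
    fuzzy_r: float = 0.15
    fuzzy_n: float = 2.0
    disp_m: int = 3
    disp_nc: int = 6
    perm_m: int = 3
    perm_tie_noise: float = 1e-6
    phase_k: int = 16
    dist_m: int = 3
    dist_bins: int = 512


@dataclass(frozen=True)
class PRSAParams:
    """Phase-rectified signal averaging parameters.

    half_window_L : beats averaged on each side of an anchor.
    anchor_filter : anchors whose relative RR change exceeds this fraction
        are excluded (guards against residual artifacts).
    """

    half_window_L: int = 8
    anchor_filter: float = 0.05


# ---------------------------------------------------------------------------
# fractal scaling
# ---------------------------------------------------------------------------

def dfa_alpha1(x: np.ndarray, scales: tuple[int, int] = (6, 14)) -> float:
    """Short-range detrended fluctuation exponent.

    The mean-centered series is integrated; for each window size ``n`` in
    ``scales`` (inclusive) the profile is split into non-overlapping windows
    (tail discarded), linearly detrended per window, and the RMS residual
    F(n) computed.  Alpha-1 is the slope of log F(n) against log n.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 100:
        raise ValueError("DFA needs at least 100 beats")
    if x.std() == 0:
        return float("nan")
    profile = np.cumsum(x - x.mean())
    ns = np.arange(scales[0], scales[1] + 1)
    fluct = np.empty(len(ns))
    for i, n in enumerate(ns):
        k = len(profile) // n
        segs = profile[: k * n].reshape(k, n)
        t = np.arange(n)
        # least-squares linear detrend of every window at once
        A = np.vstack([t, np.ones(n)]).T
        coef, *_ = np.linalg.lstsq(A, segs.T, rcond=None)
        resid = segs.T - A @ coef
        fluct[i] = np.sqrt(np.mean(resid**2))
    slope = np.polyfit(np.log(ns), np.log(fluct), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-1 embedding: rows are x[i:i+m]."""
    return np.lib.stride_tricks.sliding_window_view(x, m)


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.15) -> float:
    """Sample entropy, -ln(A/B), with tolerance ``r`` x SD (Chebyshev metric).

    A and B count template pairs (self-matches excluded) of length ``m+1``
    and ``m`` within tolerance; the same N-m-1 templates are used at both
    lengths.  A constant series yields 0; absence of any length-``m`` match
    yields ``nan``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 2:
        raise ValueError("series too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd
    emb = _embed(x, m + 1)          # N - m templates of length m+1
    d_m = pdist(emb[:, :m], metric="chebyshev")
    d_m1 = pdist(emb, metric="chebyshev")
    b = np.count_nonzero(d_m <= tol)
    a = np.count_nonzero(d_m1 <= tol)
    if b == 0 or a == 0:
        return float("nan")
    return float(-math.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r: float = 0.15, n: float = 2.0) -> float:
    """Fuzzy entropy with exponential membership exp(-(d/r)^n).

    Templates are locally centered (their own mean subtracted) before the
    Chebyshev distance; tolerance ``r`` scales with the series SD.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 2:
        raise ValueError("series too short for fuzzy entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def phi(mm: int) -> float:
        emb = _embed(x, mm)[: len(x) - m]   # same template count for m, m+1
        emb = emb - emb.mean(axis=1, keepdims=True)
        d = pdist(emb, metric="chebyshev")
        return float(np.mean(np.exp(-((d / tol) ** n))))

    return float(math.log(phi(m)) - math.log(phi(m + 1)))


def dispersion_entropy(x: np.ndarray, m: int = 3, nc: int = 6) -> float:
    """Normalized dispersion entropy (normal-CDF mapping to ``nc`` classes).

    Values are mapped through the normal CDF fitted to the series, rounded
    into ``nc`` classes, and the Shannon entropy of ``m``-long dispersion
    patterns is normalized by ln(nc^m).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 1:
        raise ValueError("series too short for dispersion entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    y = norm.cdf((x - x.mean()) / sd)
    z = np.clip(np.round(nc * y + 0.5), 1, nc).astype(int)
    patterns = _embed(z, m)
    # encode each pattern as an integer base nc
    codes = patterns @ (nc ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(nc**m))


def permutation_entropy(
    x: np.ndarray, m: int = 3, tie_noise: float = 1e-6, seed: int = 0
) -> float:
    """Normalized permutation entropy of order ``m``.

    Ordinal patterns of ``m`` consecutive values; ties are broken by adding
    uniform noise of amplitude ``tie_noise`` x SD from a fixed per-call seed
    so the estimator stays deterministic.  Normalized by ln(m!).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 1:
        raise ValueError("series too short for permutation entropy")
    sd = x.std()
    if sd > 0 and tie_noise > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.uniform(-1, 1, len(x)) * tie_noise * sd
    patterns = np.argsort(_embed(x, m), axis=1, kind="stable")
    codes = patterns @ (m ** np.arange(m))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(m)))


def phase_entropy(x: np.ndarray, k: int = 16) -> float:
    """Normalized Shannon entropy of angle-sector occupancy in the
    second-order difference plot.

    Each pair of consecutive successive-differences forms a point
    (dx_i, dx_{i+1}); its angle is assigned to one of ``k`` equal sectors of
    [0, 2*pi).  Points at the origin carry no angle and are dropped; a series
    with no off-origin point returns ``nan``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("series too short for phase entropy")
    dx = np.diff(x)
    u, v = dx[:-1], dx[1:]
    keep = (u != 0) | (v != 0)
    if not keep.any():
        return float("nan")
    theta = np.mod(np.arctan2(v[keep], u[keep]), 2 * np.pi)
    sector = np.minimum((theta / (2 * np.pi) * k).astype(int), k - 1)
    counts = np.bincount(sector, minlength=k)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / math.log(k))


def distribution_entropy(x: np.ndarray, m: int = 3, bins: int = 512) -> float:
    """Distribution entropy: normalized Shannon entropy of the histogram of
    inter-template Chebyshev distances (``bins`` bins), base 2.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < m + 1:
        raise ValueError("series too short for distribution entropy")
    if x.std() == 0:
        return float("nan")
    emb = _embed(x, m)
    d = pdist(emb, metric="chebyshev")
    counts, _ = np.histogram(d, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() / math.log2(bins))


def attention_entropy(x: np.ndarray) -> float:
    """Attention entropy: average Shannon entropy of the intervals between
    local-extrema key patterns.

    Key patterns are strict local maxima and minima.  Four interval streams
    are formed (max-max, min-min, max-min, min-max); each contributes the
    Shannon entropy (base 2) of its interval-value distribution, and the
    index is the mean of the four.  A series with no extrema returns ``nan``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("series too short for attention entropy")
    mid = x[1:-1]
    is_max = (mid > x[:-2]) & (mid > x[2:])
    is_min = (mid < x[:-2]) & (mid < x[2:])
    maxima = np.flatnonzero(is_max) + 1
    minima = np.flatnonzero(is_min) + 1
    if len(maxima) == 0 and len(minima) == 0:
        return float("nan")

    def stream_entropy(intervals: np.ndarray) -> float:
        if len(intervals) == 0:
            return 0.0
        _, counts = np.unique(intervals, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    def cross_intervals(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        # interval from each src event to the next dst event after it
        if len(src) == 0 or len(dst) == 0:
            return np.empty(0, dtype=int)
        pos = np.searchsorted(dst, src, side="right")
        ok = pos < len(dst)
        return dst[pos[ok]] - src[ok]

    ents = [
        stream_entropy(np.diff(maxima)),
        stream_entropy(np.diff(minima)),
        stream_entropy(cross_intervals(maxima, minima)),
        stream_entropy(cross_intervals(minima, maxima)),
    ]
    return float(np.mean(ents))


# ---------------------------------------------------------------------------
# symbolic dynamics
# ---------------------------------------------------------------------------

def symbolic_maxmin(x: np.ndarray) -> dict[str, float]:
    """Max-Min symbolic dynamics: six equal-width amplitude bins, 3-symbol
    words classified as 0V / 1V / 2LV / 2UV, percentages over all words.

    Returns nan for a constant (zero-range) series.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 beats for symbolic words")
    lo, hi = x.min(), x.max()
    keys = ["Symb-0V", "Symb-1V", "Symb-2LV", "Symb-2UV"]
    if hi == lo:
        return {k: float("nan") for k in keys}
    s = np.minimum((6 * (x - lo) / (hi - lo)).astype(int), 5)
    d1 = np.diff(s)[:-1]
    d2 = np.diff(s)[1:]
    n_words = len(d1)
    zero1, zero2 = d1 == 0, d2 == 0
    c0 = np.count_nonzero(zero1 & zero2)
    c1 = np.count_nonzero(zero1 ^ zero2)
    like = np.count_nonzero(~zero1 & ~zero2 & (np.sign(d1) == np.sign(d2)))
    unlike = np.count_nonzero(~zero1 & ~zero2 & (np.sign(d1) != np.sign(d2)))
    return dict(zip(keys, (100.0 * np.array([c0, c1, like, unlike]) / n_words)))


def symbolic_binary(x: np.ndarray) -> dict[str, float]:
    """Binary symbolic dynamics on the sign of successive differences.

    Symbol 1 for an increase, 0 otherwise (a zero difference counts as a
    non-increase).  3-symbol words are classified by their number of symbol
    changes (0, 1 or 2), reported as percentages.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 beats for binary symbolic words")
    b = (np.diff(x) > 0).astype(int)
    changes = (b[:-2] != b[1:-1]).astype(int) + (b[1:-1] != b[2:]).astype(int)
    n_words = len(changes)
    return {
        "Bin-0V": 100.0 * np.count_nonzero(changes == 0) / n_words,
        "Bin-1V": 100.0 * np.count_nonzero(changes == 1) / n_words,
        "Bin-2V": 100.0 * np.count_nonzero(changes == 2) / n_words,
    }


def fragmentation(x: np.ndarray) -> dict[str, float]:
    """Heart-rate fragmentation: PIP and 4-symbol word percentages W0-W3.

    Each successive difference is given a ternary symbol (+1 for a
    decreasing interval, -1 for an increasing one, 0 for no change).  Every
    transition between two *different* consecutive symbols — including
    transitions to or from 0 — is an inflection point.  PIP is the
    percentage of inflection points among all transitions; words of four
    consecutive symbols are classified by their internal inflection count.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 beats for fragmentation words")
    d = np.diff(x)
    s = np.where(d < 0, 1, np.where(d > 0, -1, 0))
    flips = (s[:-1] != s[1:]).astype(int)
    pip = 100.0 * flips.sum() / len(flips)
    # 4-symbol words contain 3 transitions
    counts_in_word = flips[:-2] + flips[1:-1] + flips[2:]
    n_words = len(counts_in_word)
    out = {"HRF-PIP": float(pip)}
    for w in range(4):
        out[f"HRF-W{w}"] = 100.0 * np.count_nonzero(counts_in_word == w) / n_words
    return out


# ---------------------------------------------------------------------------
# asymmetry and PRSA
# ---------------------------------------------------------------------------

def asymmetry(x: np.ndarray) -> dict[str, float]:
    """Time-irreversibility indices of the successive-difference distribution.

    Porta: percentage of negative differences among nonzero ones.
    Guzik: percentage of the squared-difference energy carried by positive
    differences.  Ehlers: skewness-like ratio sum(d^3) / sum(d^2)^(3/2).
    Both Porta and Guzik equal 50 and Ehlers equals 0 for a time-reversible
    series.  All three are nan when every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 beats for asymmetry indices")
    d = np.diff(x)
    nz = d[d != 0]
    if len(nz) == 0:
        return {"Porta": float("nan"), "Guzik": float("nan"), "Ehlers": float("nan")}
    porta = 100.0 * np.count_nonzero(nz < 0) / len(nz)
    guzik = 100.0 * (nz[nz > 0] ** 2).sum() / (nz**2).sum()
    ehlers = (d**3).sum() / (d**2).sum() ** 1.5
    return {"Porta": float(porta), "Guzik": float(guzik), "Ehlers": float(ehlers)}


def prsa_acdc(x: np.ndarray, params: PRSAParams = PRSAParams()) -> dict[str, float]:
    """Acceleration and deceleration capacity by phase-rectified signal
    averaging.

    Anchors are beats longer (deceleration) or shorter (acceleration) than
    their predecessor; anchors changing by more than ``anchor_filter`` of the
    previous interval are excluded, as are anchors whose +/-L window leaves
    the series.  Windows are averaged aligned on the anchor and the capacity
    is the 4-point Haar-like difference (X(0) + X(1) - X(-1) - X(-2)) / 4.
    ``nan`` when no valid anchor exists.
    """
    x = np.asarray(x, dtype=float)
    L = params.half_window_L
    if len(x) < 2 * L + 2:
        raise ValueError(f"PRSA needs at least {2 * L + 2} beats")

    def capacity(decel: bool) -> float:
        prev = x[:-1]
        cur = x[1:]
        sel = (cur > prev) if decel else (cur < prev)
        sel &= np.abs(cur - prev) <= params.anchor_filter * prev
        anchors = np.flatnonzero(sel) + 1
        anchors = anchors[(anchors >= L) & (anchors + L - 1 < len(x))]
        if len(anchors) == 0:
            return float("nan")
        offsets = np.arange(-L, L)
        windows = x[anchors[:, None] + offsets[None, :]]
        prof = windows.mean(axis=0)  # prof[L + k] == X(k)
        return float((prof[L] + prof[L + 1] - prof[L - 1] - prof[L - 2]) / 4.0)

    return {"AC": capacity(decel=False), "DC": capacity(decel=True)}


# ---------------------------------------------------------------------------
# aggregate
# ---------------------------------------------------------------------------

def nonlinear_indices(
    x: np.ndarray,
    entropy_params: EntropyParams = EntropyParams(),
    prsa_params: PRSAParams = PRSAParams(),
) -> dict[str, float]:
    """All 25 nonlinear indices for one RR-interval segment, keyed by the
    feature-table column names."""
    x = np.asarray(x, dtype=float)
    p = entropy_params
    out: dict[str, float] = {"DFA-a1": dfa_alpha1(x)}
    out["SampEn"] = sample_entropy(x, p.sampen_m, p.sampen_r)
    out["FuzzyEn"] = fuzzy_entropy(x, p.fuzzy_m, p.fuzzy_r, p.fuzzy_n)
    out["DispEn"] = dispersion_entropy(x, p.disp_m, p.disp_nc)
    out["PhaseEn"] = phase_entropy(x, p.phase_k)
    out["DistEn"] = distribution_entropy(x, p.dist_m, p.dist_bins)
    out["PermEn"] = permutation_entropy(x, p.perm_m, p.perm_tie_noise)
    out["AttEn"] = attention_entropy(x)
    out.update(symbolic_maxmin(x))
    out.update(symbolic_binary(x))
    out.update(fragmentation(x))
    out.update(asymmetry(x))
    out.update(prsa_acdc(x, prsa_params))
    return out
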