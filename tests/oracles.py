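"""Independent brute-force reference implementations.

Every function here is written as a direct, loop-based transcription of the
index definition, deliberately sharing no code with the package, so that
agreement between the two routes is meaningful.  They are O(N^2) or worse
and intended for short series only.
"""

from __future__ import annotations

import math

import numpy as np


def _cheb(a, b) -> float:
    return max(abs(x - y) for x, y in zip(a, b))


def brute_sampen(x: np.ndarray, m: int = 2, r: float = 0.15) -> float:
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()
    b_count = a_count = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if _cheb(x[i:i + m], x[j:j + m]) <= tol:
                b_count += 1
            if _cheb(x[i:i + m + 1], x[j:j + m + 1]) <= tol:
                a_count += 1
    if a_count == 0 or b_count == 0:
        return float("nan")
    return -math.log(a_count / b_count)


def brute_fuzzy(x: np.ndarray, m: int = 2, r: float = 0.15, nexp: float = 2.0) -> float:
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()

    def phi(mm: int) -> float:
        temps = [x[i:i + mm] - x[i:i + mm].mean() for i in range(n - m)]
        sims = []
        for i in range(len(temps)):
            for j in range(i + 1, len(temps)):
                d = _cheb(temps[i], temps[j])
                sims.append(math.exp(-((d / tol) ** nexp)))
        return float(np.mean(sims))

    return math.log(phi(m)) - math.log(phi(m + 1))


def brute_dispen(x: np.ndarray, m: int = 3, nc: int = 6) -> float:
    from scipy.stats import norm

    x = np.asarray(x, float)
    y = norm.cdf((x - x.mean()) / x.std())
    z = [min(max(int(round(nc * v + 0.5)), 1), nc) for v in y]
    patterns: dict[tuple, int] = {}
    for i in range(len(z) - m + 1):
        key = tuple(z[i:i + m])
        patterns[key] = patterns.get(key, 0) + 1
    total = sum(patterns.values())
    ent = -sum((c / total) * math.log(c / total) for c in patterns.values())
    return ent / math.log(nc**m)


def brute_permen(x: np.ndarray, m: int = 3) -> float:
    """Ordinal-pattern entropy assuming no ties in the input."""
    x = np.asarray(x, float)
    patterns: dict[tuple, int] = {}
    for i in range(len(x) - m + 1):
        window = x[i:i + m]
        key = tuple(sorted(range(m), key=lambda k: window[k]))
        patterns[key] = patterns.get(key, 0) + 1
    total = sum(patterns.values())
    ent = -sum((c / total) * math.log(c / total) for c in patterns.values())
    return ent / math.log(math.factorial(m))


def brute_maxmin(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, float)
    lo, hi = x.min(), x.max()
    sym = [min(int(6 * (v - lo) / (hi - lo)), 5) for v in x]
    counts = {"Symb-0V": 0, "Symb-1V": 0, "Symb-2LV": 0, "Symb-2UV": 0}
    n_words = len(sym) - 2
    for i in range(n_words):
        a, b, c = sym[i], sym[i + 1], sym[i + 2]
        d1, d2 = b - a, c - b
        if d1 == 0 and d2 == 0:
            counts["Symb-0V"] += 1
        elif (d1 == 0) != (d2 == 0):
            counts["Symb-1V"] += 1
        elif (d1 > 0) == (d2 > 0):
            counts["Symb-2LV"] += 1
        else:
            counts["Symb-2UV"] += 1
    return {k: 100.0 * v / n_words for k, v in counts.items()}


def brute_binary(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, float)
    b = [1 if x[i + 1] - x[i] > 0 else 0 for i in range(len(x) - 1)]
    counts = [0, 0, 0]
    n_words = len(b) - 2
    for i in range(n_words):
        changes = int(b[i] != b[i + 1]) + int(b[i + 1] != b[i + 2])
        counts[changes] += 1
    return {f"Bin-{k}V": 100.0 * counts[k] / n_words for k in range(3)}


def brute_hrf(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, float)
    d = np.diff(x)
    s = [1 if v < 0 else (-1 if v > 0 else 0) for v in d]
    inflections = [int(s[i] != s[i + 1]) for i in range(len(s) - 1)]
    pip = 100.0 * sum(inflections) / len(inflections)
    out = {"HRF-PIP": pip}
    word_counts = [0, 0, 0, 0]
    n_words = len(s) - 3
    for i in range(n_words):
        k = sum(int(s[i + j] != s[i + j + 1]) for j in range(3))
        word_counts[k] += 1
    for w in range(4):
        out[f"HRF-W{w}"] = 100.0 * word_counts[w] / n_words
    return out


def brute_asymmetry(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, float)
    d = np.diff(x)
    nz = [v for v in d if v != 0]
    porta = 100.0 * sum(1 for v in nz if v < 0) / len(nz)
    guzik = 100.0 * sum(v**2 for v in nz if v > 0) / sum(v**2 for v in nz)
    ehlers = sum(v**3 for v in d) / sum(v**2 for v in d) ** 1.5
    return {"Porta": porta, "Guzik": guzik, "Ehlers": ehlers}


def brute_prsa(x: np.ndarray, L: int = 8, anchor_filter: float = 0.05) -> dict[str, float]:
    x = np.asarray(x, float)
    out = {}
    for name, decel in (("AC", False), ("DC", True)):
        windows = []
        for i in range(1, len(x)):
            if decel and not x[i] > x[i - 1]:
                continue
            if not decel and not x[i] < x[i - 1]:
                continue
            if abs(x[i] - x[i - 1]) > anchor_filter * x[i - 1]:
                continue
            if i - L < 0 or i + L - 1 >= len(x):
                continue
            windows.append(x[i - L:i + L])
        if not windows:
            out[name] = float("nan")
            continue
        prof = np.mean(windows, axis=0)  # prof[L + k] = X(k)
        out[name] = (prof[L] + prof[L + 1] - prof[L - 1] - prof[L - 2]) / 4.0
    return out


def brute_auroc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney U / (n_pos * n_neg), ties counted half."""
    pos = scores[np.asarray(y) == 1]
    neg = scores[np.asarray(y) == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def brute_delong_components(y: np.ndarray, scores: np.ndarray):
    """Structural components of the AUROC via the O(n^2) placement kernel.

    Returns (auc, V10, V01) where V10[i] = mean_j psi(x_i, y_j) over
    negatives and V01[j] = mean_i psi(x_i, y_j) over positives.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, float)
    xs = scores[y == 1]
    ys = scores[y == 0]

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    v10 = np.array([np.mean([psi(a, b) for b in ys]) for a in xs])
    v01 = np.array([np.mean([psi(a, b) for a in xs]) for b in ys])
    return v10.mean(), v10, v01
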