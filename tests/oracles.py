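"""Independent brute-force reference implementations used only by tests.

Every function here follows the textbook definition with plain Python
loops, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def shoelace_area(points: np.ndarray) -> float:
    n = len(points)
    s = 0.0
    for i in range(n):
        x1, y1 = points[i]
        x2, y2 = points[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def pair_count_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney probability with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def firstorder_reference(values: np.ndarray, n_levels: int = 32) -> dict:
    """The 18 first-order statistics, computed by definition."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    lo, hi = x[0], x[-1]
    if hi - lo < 1e-12:
        hist = [n]
    else:
        hist = [0] * n_levels
        for v in x:
            b = int((v - lo) / (hi - lo) * n_levels)
            hist[min(b, n_levels - 1)] += 1
    probs = [h / n for h in hist if h > 0]
    entropy = -sum(p * math.log2(p) for p in probs)
    uniformity = sum(p * p for p in probs)
    p10, p25, p50, p75, p90 = (float(np.percentile(values, q)) for q in (10, 25, 50, 75, 90))
    core = [v for v in x if p10 <= v <= p90]
    core_mean = sum(core) / len(core) if core else 0.0
    return {
        "Energy": sum(v * v for v in x),
        "TotalEnergy": sum(v * v for v in x),
        "Entropy": entropy,
        "Minimum": lo,
        "P10": p10,
        "P90": p90,
        "Maximum": hi,
        "Mean": mean,
        "Median": p50,
        "IQR": p75 - p25,
        "Range": hi - lo,
        "MAD": sum(abs(v - mean) for v in x) / n,
        "rMAD": sum(abs(v - core_mean) for v in core) / len(core) if core else 0.0,
        "RMS": math.sqrt(sum(v * v for v in x) / n),
        "Skewness": (sum((v - mean) ** 3 for v in x) / n) / sd**3 if sd > 0 else 0.0,
        "Kurtosis": (sum((v - mean) ** 4 for v in x) / n) / sd**4 if sd > 0 else 0.0,
        "Variance": var,
        "Uniformity": uniformity,
    }


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_reference(levels: np.ndarray, mask: np.ndarray, ng: int,
                   angle: int, distance: int = 1) -> dict:
    """Symmetric masked GLCM features by pairwise enumeration."""
    h, w = mask.shape
    dr, dc = (d * distance for d in _OFFSETS[angle])
    counts = {}
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = int(levels[r, c]), int(levels[r2, c2])
                counts[(i, j)] = counts.get((i, j), 0) + 1
                counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in ("contrast", "dissimilarity", "homogeneity",
                                 "asm", "entropy", "correlation", "shade", "prominence")}
    P = {k: v / total for k, v in counts.items()}
    mu_x = sum(i * p for (i, j), p in P.items())
    mu_y = sum(j * p for (i, j), p in P.items())
    var_x = sum((i - mu_x) ** 2 * p for (i, j), p in P.items())
    var_y = sum((j - mu_y) ** 2 * p for (i, j), p in P.items())
    if var_x > 0 and var_y > 0:
        corr = sum((i - mu_x) * (j - mu_y) * p for (i, j), p in P.items()) / math.sqrt(var_x * var_y)
    else:
        corr = 1.0
    return {
        "contrast": sum((i - j) ** 2 * p for (i, j), p in P.items()),
        "dissimilarity": sum(abs(i - j) * p for (i, j), p in P.items()),
        "homogeneity": sum(p / (1 + (i - j) ** 2) for (i, j), p in P.items()),
        "asm": sum(p * p for p in P.values()),
        "entropy": -sum(p * math.log2(p) for p in P.values() if p > 0),
        "correlation": corr,
        "shade": sum((i + j - mu_x - mu_y) ** 3 * p for (i, j), p in P.items()),
        "prominence": sum((i + j - mu_x - mu_y) ** 4 * p for (i, j), p in P.items()),
    }


def ngtdm_reference(levels: np.ndarray, mask: np.ndarray, ng: int,
                    eps: float = 1e-6, cap: float = 1e6) -> dict:
    """NGTDM features by per-pixel neighborhood enumeration."""
    h, w = mask.shape
    s = [0.0] * (ng + 1)
    n = [0] * (ng + 1)
    N = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        nb.append(int(levels[r2, c2]))
            if not nb:
                continue
            i = int(levels[r, c])
            s[i] += abs(i - sum(nb) / len(nb))
            n[i] += 1
            N += 1
    if N == 0:
        return {k: 0.0 for k in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p = [ni / N for ni in n]
    present = [i for i in range(1, ng + 1) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in present)
    coarse = min(1.0 / (eps + ps), cap)
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (sum(s[i] for i in present) / N)
        denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
        busy = ps / denom if denom > 0 else 0.0
        cplx = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / N
        strength = sum(
            (p[i] + p[j]) * (i - j) ** 2 for i in present for j in present
        ) / (eps + sum(s[i] for i in present))
    else:
        contrast = busy = cplx = strength = 0.0
    return {"Coarseness": coarse, "Contrast": contrast, "Busyness": busy,
            "Complexity": cplx, "Strength": strength}


def plugin_mi_reference(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in MI with equal-frequency binning, by histogram enumeration."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.digitize(x, edges)
    n = len(x)
    mi = 0.0
    for b in set(bins.tolist()):
        for c in (0, 1):
            nxy = sum(1 for bb, cc in zip(bins, y) if bb == b and cc == c)
            if nxy == 0:
                continue
            nx = sum(1 for bb in bins if bb == b)
            ny = sum(1 for cc in y if cc == c)
            mi += (nxy / n) * math.log2((nxy / n) / ((nx / n) * (ny / n)))
    return max(mi, 0.0)


def ppa_weight_reference(channel, inside, xs, ys, u) -> float:
    """PPAweight by per-ray loops with bilinear sampling."""
    from scipy.ndimage import map_coordinates

    vals = []
    for ray in range(inside.shape[0]):
        idx = np.nonzero(inside[ray])[0]
        if len(idx) < 2:
            continue
        t = np.linspace(idx[0], idx[-1], u)
        x = np.interp(t, np.arange(inside.shape[1]), xs[ray])
        y = np.interp(t, np.arange(inside.shape[1]), ys[ray])
        prof = map_coordinates(channel, [y - 0.5, x - 0.5], order=1, mode="nearest")
        vals.append(float(np.abs(np.diff(prof)).mean()))
    return float(np.mean(vals)) if vals else 0.0
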