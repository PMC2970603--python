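"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain loops over pixels / runs / sign
patterns, deliberately sharing no code with the package, so that agreement
with the vectorised implementations is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------

def glcm_matrix_bruteforce(levels: dict, offset: tuple[int, int], n_levels: int):
    """levels: {(row, col): level}.  Counts ordered pairs along +/- offset."""
    dx, dy = offset
    dr, dc = -dy, dx
    counts = np.zeros((n_levels, n_levels))
    for (r, c), g in levels.items():
        for sr, sc in ((dr, dc), (-dr, -dc)):
            other = levels.get((r + sr, c + sc))
            if other is not None:
                counts[g - 1, other - 1] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def haralick_bruteforce(p: np.ndarray) -> dict:
    ng = p.shape[0]
    asm = contrast = idm = ent = 0.0
    mu_x = mu_y = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            mu_x += (i + 1) * v
            mu_y += (j + 1) * v
    var_x = var_y = corr_num = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            asm += v * v
            contrast += (i - j) ** 2 * v
            idm += v / (1 + (i - j) ** 2)
            if v > 0:
                ent -= v * math.log(v)
            var_x += (i + 1 - mu_x) ** 2 * v
            var_y += (j + 1 - mu_y) ** 2 * v
            corr_num += (i + 1) * (j + 1) * v
    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i, j]
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    sum_ent = -sum(v * math.log(v) for v in p_sum.values() if v > 0)
    dif_mean = sum(k * v for k, v in p_diff.items())
    dif_var = sum((k - dif_mean) ** 2 * v for k, v in p_diff.items())
    dif_ent = -sum(v * math.log(v) for v in p_diff.values() if v > 0)
    sd = math.sqrt(var_x * var_y)
    return {
        "AngScMom": asm,
        "Contrast": contrast,
        "Correlat": (corr_num - mu_x * mu_y) / sd if sd > 0 else float("nan"),
        "SumOfSqs": var_x,
        "InvDfMom": idm,
        "SumAverg": sum_avg,
        "SumVarnc": sum_var,
        "SumEntrp": sum_ent,
        "Entropy": ent,
        "DifVarnc": dif_var,
        "DifEntrp": dif_ent,
    }


# ---------------------------------------------------------------------------
# run lengths
# ---------------------------------------------------------------------------

_RLM_STEPS = {"Horzl": (0, 1), "Vertl": (1, 0), "45dgr": (-1, 1), "135dr": (1, 1)}


def rlm_bruteforce(levels: dict, direction: str, n_pixels: int) -> dict:
    """Walks every maximal run pixel by pixel."""
    dr, dc = _RLM_STEPS[direction]
    runs = []
    for (r, c), g in levels.items():
        prev = levels.get((r - dr, c - dc))
        if prev == g:
            continue  # not a run start
        length = 1
        rr, cc = r + dr, c + dc
        while levels.get((rr, cc)) == g:
            length += 1
            rr, cc = rr + dr, cc + dc
        runs.append((g, length))
    if not runs:
        return {k: float("nan") for k in
                ("ShrtREmph", "LngREmph", "GLevNonUni", "RLNonUni", "Fraction")}
    n = len(runs)
    by_level: dict[int, int] = {}
    by_length: dict[int, int] = {}
    for g, l in runs:
        by_level[g] = by_level.get(g, 0) + 1
        by_length[l] = by_length.get(l, 0) + 1
    return {
        "ShrtREmph": sum(1.0 / l ** 2 for _, l in runs) / n,
        "LngREmph": sum(float(l ** 2) for _, l in runs) / n,
        "GLevNonUni": sum(v ** 2 for v in by_level.values()) / n,
        "RLNonUni": sum(v ** 2 for v in by_length.values()) / n,
        "Fraction": n / n_pixels,
    }


# ---------------------------------------------------------------------------
# first-order
# ---------------------------------------------------------------------------

def histogram_bruteforce(values) -> dict:
    x = [float(v) for v in values]
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    out = {
        "Mean": mean,
        "Variance": m2,
        "Skewness": m3 / m2 ** 1.5 if m2 > 0 else float("nan"),
        "Kurtosis": m4 / m2 ** 2 - 3.0 if m2 > 0 else float("nan"),
    }
    xs = sorted(x)
    for p in (1, 10, 25, 50, 75, 90, 99):
        k = max(1, math.ceil(p / 100 * n))
        out[f"Perc{p:02d}"] = xs[k - 1]
    return out


def gradient_values_bruteforce(values: dict) -> list[float]:
    """values: {(row, col): clipped intensity}; returns per-interior-pixel gradients."""
    out = []
    for (r, c) in sorted(values):
        try:
            below = values[(r + 1, c)]
            above = values[(r - 1, c)]
            right = values[(r, c + 1)]
            left = values[(r, c - 1)]
        except KeyError:
            continue
        out.append(math.sqrt(((below - above) / 2) ** 2 + ((right - left) / 2) ** 2))
    return out


# ---------------------------------------------------------------------------
# wavelet: direct 2x2 block filter (orthonormal Haar, scale 1)
# ---------------------------------------------------------------------------

def wavelet_bruteforce(img: np.ndarray, mask: np.ndarray) -> dict:
    """img already mean-filled and even-sized; energies over mask-overlap blocks."""
    h2, w2 = img.shape[0] // 2, img.shape[1] // 2
    bands = {"WavEnLL": [], "WavEnLH": [], "WavEnHL": [], "WavEnHH": []}
    for i in range(h2):
        for j in range(w2):
            blk = img[2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
            if not mask[2 * i : 2 * i + 2, 2 * j : 2 * j + 2].any():
                continue
            a, b = blk[0, 0], blk[0, 1]
            c, d = blk[1, 0], blk[1, 1]
            bands["WavEnLL"].append(((a + b + c + d) / 2) ** 2)
            bands["WavEnLH"].append(((a + b - c - d) / 2) ** 2)  # row difference
            bands["WavEnHL"].append(((a - b + c - d) / 2) ** 2)  # column difference
            bands["WavEnHH"].append(((a - b - c + d) / 2) ** 2)
    return {k: (sum(v) / len(v) if v else float("nan")) for k, v in bands.items()}


# ---------------------------------------------------------------------------
# Wilcoxon signed ranks: literal enumeration of all 2^n sign patterns
# ---------------------------------------------------------------------------

def wilcoxon_exact_bruteforce(differences) -> float:
    d = [v for v in differences if v != 0]
    n = len(d)
    absd = [abs(v) for v in d]
    # mid-ranks
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    le = ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    total = 2 ** n
    return min(1.0, 2.0 * min(le / total, ge / total))
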