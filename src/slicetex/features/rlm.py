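"""Run-length matrices and their five classical features.

A run is a maximal sequence of in-mask pixels with equal quantized level
along one of four directions (horizontal, vertical, and the two diagonals).
Runs are truncated at the mask boundary, so irregular ROI shapes shorten
runs rather than borrowing pixels from outside the ROI.
"""

from __future__ import annotations

import numpy as np

from ..roi import QuantizedRoi
from .names import RLM_DIRECTIONS, RLM_FEATURES, rlm_name

# direction name -> (drow, dcol) step in array coordinates
_STEPS = {
    "Horzl": (0, 1),
    "Vertl": (1, 0),
    "45dgr": (-1, 1),  # up-right
    "135dr": (1, 1),   # down-right
}


def _runs_1d(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal equal-level in-mask runs along one line."""
    n = values.size
    if n == 0 or not mask.any():
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    cont = mask[1:] & mask[:-1] & (values[1:] == values[:-1])
    starts = mask & np.concatenate(([True], ~cont))
    start_idx = np.flatnonzero(starts)
    brk = np.flatnonzero(~cont)  # run cannot continue across position brk -> brk+1
    end_idx = np.empty_like(start_idx)
    pos = np.searchsorted(brk, start_idx)
    end_idx[pos < brk.size] = brk[pos[pos < brk.size]]
    end_idx[pos >= brk.size] = n - 1
    return values[start_idx].astype(np.int64), (end_idx - start_idx + 1).astype(np.int64)


def _lines(levels: np.ndarray, mask: np.ndarray, direction: str):
    if direction == "Horzl":
        for r in range(levels.shape[0]):
            yield levels[r], mask[r]
    elif direction == "Vertl":
        for c in range(levels.shape[1]):
            yield levels[:, c], mask[:, c]
    else:
        lv = np.flipud(levels) if direction == "45dgr" else levels
        mk = np.flipud(mask) if direction == "45dgr" else mask
        h, w = lv.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(lv, off), np.diagonal(mk, off)


def run_lengths(roi: QuantizedRoi, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated (levels, lengths) of every run in the ROI along direction."""
    if direction not in _STEPS:
        raise ValueError(f"unknown run-length direction {direction!r}")
    levels, mask = roi.level_image()
    gs, ls = [], []
    for v, m in _lines(levels, mask, direction):
        g, l = _runs_1d(np.ascontiguousarray(v), np.ascontiguousarray(m))
        if g.size:
            gs.append(g)
            ls.append(l)
    if not gs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(gs), np.concatenate(ls)


def rlm_features_direction(roi: QuantizedRoi, direction: str) -> dict[str, float]:
    """ShrtREmph, LngREmph, GLevNonUni, RLNonUni and Fraction for one direction."""
    if roi.degenerate:
        return {f: float("nan") for f in RLM_FEATURES}
    g, l = run_lengths(roi, direction)
    n_runs = g.size
    if n_runs == 0:
        return {f: float("nan") for f in RLM_FEATURES}
    lf = l.astype(np.float64)
    glev_counts = np.bincount(g)
    rl_counts = np.bincount(l)
    return {
        "ShrtREmph": float((1.0 / lf ** 2).sum() / n_runs),
        "LngREmph": float((lf ** 2).sum() / n_runs),
        "GLevNonUni": float((glev_counts.astype(np.float64) ** 2).sum() / n_runs),
        "RLNonUni": float((rl_counts.astype(np.float64) ** 2).sum() / n_runs),
        "Fraction": float(n_runs / roi.n_pixels),
    }


def rlm_feature_block(roi: QuantizedRoi) -> dict[str, float]:
    """All 20 run-length features (4 directions x 5 features)."""
    out: dict[str, float] = {}
    for d in RLM_DIRECTIONS:
        feats = rlm_features_direction(roi, d)
        for f in RLM_FEATURES:
            out[rlm_name(d, f)] = feats[f]
    return out
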