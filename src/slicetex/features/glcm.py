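"""Grey-level co-occurrence matrices and the 11 Haralick-type features.

Matrices are ROI-confined: a pixel pair contributes only if *both* endpoints
lie inside the (possibly irregular) ROI mask, so irregular masks never leak
neighbouring tissue into the statistics.  Matrices are symmetric (each
ordered pair is counted along +offset and -offset) and normalised to sum 1.
Entropies use the natural logarithm with 0*log(0) := 0.
"""

from __future__ import annotations

import numpy as np

from ..roi import QuantizedRoi
from .names import GLCM_FEATURES, glcm_name, glcm_offsets


def _offset_to_shift(dx: int, dy: int) -> tuple[int, int]:
    """(dx, dy) with dy measured upward -> (drow, dcol) in array coordinates."""
    return -dy, dx


def cooccurrence_matrix(roi: QuantizedRoi, offset: tuple[int, int]) -> np.ndarray | None:
    """Normalised symmetric co-occurrence matrix p(i, j), i, j in 1..Ng.

    Returns None when the ROI admits no pixel pair at this offset (the 11
    dependent features are then undefined).
    """
    dx, dy = offset
    if dx == 0 and dy == 0:
        raise ValueError("offset must be nonzero")
    dr, dc = _offset_to_shift(dx, dy)
    levels, mask = roi.level_image()
    h, w = mask.shape
    r_src = slice(max(0, -dr), h - max(0, dr))
    c_src = slice(max(0, -dc), w - max(0, dc))
    r_dst = slice(max(0, dr), h - max(0, -dr))
    c_dst = slice(max(0, dc), w - max(0, -dc))
    valid = mask[r_src, c_src] & mask[r_dst, c_dst]
    if not valid.any():
        return None
    a = levels[r_src, c_src][valid] - 1
    b = levels[r_dst, c_dst][valid] - 1
    ng = roi.n_levels
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    sym = counts + counts.T
    return sym / sym.sum()


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 11 classical features of one normalised co-occurrence matrix."""
    total = p.sum()
    if not np.isclose(total, 1.0, rtol=0, atol=1e-8):
        raise ValueError(f"co-occurrence matrix is not normalised (sum {total})")
    ng = p.shape[0]
    idx = np.arange(1, ng + 1, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(idx @ px)
    mu_y = float(idx @ py)
    var_x = float(((idx - mu_x) ** 2) @ px)
    var_y = float(((idx - mu_y) ** 2) @ py)

    ang_sc_mom = float((p ** 2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    denom = np.sqrt(var_x * var_y)
    if denom == 0.0:
        correlat = float("nan")
    else:
        correlat = float(((i * j * p).sum() - mu_x * mu_y) / denom)
    inv_df_mom = float((p / (1.0 + (i - j) ** 2)).sum())

    # distributions of i + j (2..2Ng) and |i - j| (0..Ng-1)
    sums = (np.arange(ng)[:, None] + np.arange(ng)[None, :]).ravel()
    p_sum = np.bincount(sums, weights=p.ravel(), minlength=2 * ng - 1)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    diffs = np.abs(np.arange(ng)[:, None] - np.arange(ng)[None, :]).ravel()
    p_diff = np.bincount(diffs, weights=p.ravel(), minlength=ng)
    k_diff = np.arange(ng, dtype=np.float64)

    sum_averg = float(k_sum @ p_sum)
    sum_varnc = float(((k_sum - sum_averg) ** 2) @ p_sum)
    dif_mean = float(k_diff @ p_diff)
    dif_varnc = float(((k_diff - dif_mean) ** 2) @ p_diff)

    return {
        "AngScMom": ang_sc_mom,
        "Contrast": contrast,
        "Correlat": correlat,
        "SumOfSqs": var_x,
        "InvDfMom": inv_df_mom,
        "SumAverg": sum_averg,
        "SumVarnc": sum_varnc,
        "SumEntrp": _entropy(p_sum),
        "Entropy": _entropy(p),
        "DifVarnc": dif_varnc,
        "DifEntrp": _entropy(p_diff),
    }


def glcm_feature_block(roi: QuantizedRoi) -> dict[str, float]:
    """All 220 co-occurrence features (5 distances x 4 directions x 11).

    Degenerate ROIs, and offsets admitting no pixel pair, yield NaN (the
    explicit undefined marker) for the dependent features.
    """
    out: dict[str, float] = {}
    for dx, dy in glcm_offsets():
        if roi.degenerate:
            feats = None
        else:
            p = cooccurrence_matrix(roi, (dx, dy))
            feats = None if p is None else haralick_features(p)
        for f in GLCM_FEATURES:
            out[glcm_name(dx, dy, f)] = float("nan") if feats is None else feats[f]
    return out
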