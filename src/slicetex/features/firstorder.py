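"""Histogram and absolute-gradient features.

Both families operate on the normalised (clipped) but unquantized ROI
intensities.  The histogram group is four moments plus seven nearest-rank
percentiles (1, 10, 25, 50, 75, 90, 99); the gradient group is the four
moments of the central-difference absolute gradient over pixels whose four
axial neighbours all lie inside the mask.  Skewness and (excess) kurtosis of
a zero-variance sample are undefined and reported as NaN.
"""

from __future__ import annotations

import math

import numpy as np

from ..roi import QuantizedRoi
from .names import GRADIENT_FEATURES, HISTOGRAM_PERCENTILES


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population variance, skewness and excess kurtosis."""
    mean = float(x.mean())
    d = x - mean
    m2 = float((d ** 2).mean())
    if m2 == 0.0:
        return mean, 0.0, float("nan"), float("nan")
    m3 = float((d ** 3).mean())
    m4 = float((d ** 4).mean())
    return mean, m2, m3 / m2 ** 1.5, m4 / m2 ** 2 - 3.0


def nearest_rank_percentile(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    n = sorted_values.size
    k = max(1, math.ceil(p / 100.0 * n))
    return float(sorted_values[k - 1])


def histogram_features(values: np.ndarray) -> dict[str, float]:
    if values.size == 0:
        raise ValueError("ROI is empty")
    mean, var, skew, kurt = _moments(values.astype(np.float64))
    out = {"Mean": mean, "Variance": var, "Skewness": skew, "Kurtosis": kurt}
    xs = np.sort(values.astype(np.float64))
    for p in HISTOGRAM_PERCENTILES:
        out[f"Perc{p:02d}"] = nearest_rank_percentile(xs, p)
    return out


def absolute_gradients(roi: QuantizedRoi) -> np.ndarray:
    """Central-difference absolute gradient at fully interior mask pixels."""
    v, m = roi.value_image()
    pad_v = np.pad(v, 1)
    pad_m = np.pad(m, 1)
    interior = (
        m
        & pad_m[2:, 1:-1] & pad_m[:-2, 1:-1]
        & pad_m[1:-1, 2:] & pad_m[1:-1, :-2]
    )
    if not interior.any():
        return np.empty(0)
    d_vert = (pad_v[2:, 1:-1] - pad_v[:-2, 1:-1]) / 2.0  # below - above
    d_horz = (pad_v[1:-1, 2:] - pad_v[1:-1, :-2]) / 2.0  # right - left
    return np.hypot(d_vert, d_horz)[interior]


def gradient_features(roi: QuantizedRoi) -> dict[str, float]:
    g = absolute_gradients(roi)
    if g.size == 0:
        return {f: float("nan") for f in GRADIENT_FEATURES}
    mean, var, skew, kurt = _moments(g)
    return {"GrMean": mean, "GrVariance": var, "GrSkewness": skew, "GrKurtosis": kurt}
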