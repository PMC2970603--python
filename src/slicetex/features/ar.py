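"""Causal autoregressive texture parameters.

The model x(s) = th1*x(left) + th2*x(upper-left) + th3*x(upper) +
th4*x(upper-right) + e(s) is fitted by ordinary least squares over every
mask pixel whose four causal neighbours also lie inside the mask, on
mean-centred (clipped) intensities.  Sigma is the population standard
deviation of the residuals.  Rank-deficient normal equations (e.g. a
constant ROI) and ROIs with fewer than ``min_pixels`` qualifying pixels
yield NaN for all five parameters.
"""

from __future__ import annotations

import numpy as np

from ..roi import QuantizedRoi
from .names import AR_FEATURES

# causal neighbourhood in array coordinates (drow, dcol)
_NEIGHBOURS = ((0, -1), (-1, -1), (-1, 0), (-1, 1))

_UNDEFINED = {f: float("nan") for f in AR_FEATURES}


def ar_features(roi: QuantizedRoi, min_pixels: int = 20) -> dict[str, float]:
    v, m = roi.value_image()
    x = np.where(m, v - float(roi.clipped.mean()), 0.0)
    pad_x = np.pad(x, 1)
    pad_m = np.pad(m, 1)

    valid = m.copy()
    cols = []
    for dr, dc in _NEIGHBOURS:
        nm = pad_m[1 + dr : 1 + dr + m.shape[0], 1 + dc : 1 + dc + m.shape[1]]
        valid &= nm
        cols.append(pad_x[1 + dr : 1 + dr + m.shape[0], 1 + dc : 1 + dc + m.shape[1]])
    n = int(valid.sum())
    if n < min_pixels:
        return dict(_UNDEFINED)
    design = np.column_stack([c[valid] for c in cols])
    target = x[valid]
    theta, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < 4:
        return dict(_UNDEFINED)
    resid = target - design @ theta
    return {
        "Teta1": float(theta[0]),
        "Teta2": float(theta[1]),
        "Teta3": float(theta[2]),
        "Teta4": float(theta[3]),
        "Sigma": float(np.sqrt((resid ** 2).mean())),
    }
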