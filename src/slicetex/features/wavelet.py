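"""Single-scale Haar sub-band energies.

The ROI's bounding box (mask-exterior pixels filled with the ROI mean, and
padded with the mean to even dimensions) is decomposed with a one-level
orthonormal Haar transform; the energy of each sub-band (LL, LH, HL, HH) is
the mean of the squared coefficients whose 2x2 pixel support overlaps the
mask.  Haar is the smallest-support wavelet, which minimises contamination
from the mean-filled exterior at the mask boundary.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..roi import QuantizedRoi
from .names import WAVELET_FEATURES


def wavelet_features(roi: QuantizedRoi) -> dict[str, float]:
    v, m = roi.value_image()
    roi_mean = float(roi.clipped.mean())
    img = np.where(m, v, roi_mean)
    h, w = img.shape
    if h < 2 or w < 2:
        return {f: float("nan") for f in WAVELET_FEATURES}
    if h % 2:
        img = np.vstack([img, np.full((1, img.shape[1]), roi_mean)])
        m = np.vstack([m, np.zeros((1, m.shape[1]), dtype=bool)])
    if w % 2:
        img = np.hstack([img, np.full((img.shape[0], 1), roi_mean)])
        m = np.hstack([m, np.zeros((m.shape[0], 1), dtype=bool)])
    ll, (lh, hl, hh) = pywt.dwt2(img, "haar", mode="periodization")
    h2, w2 = ll.shape
    overlap = m.reshape(h2, 2, w2, 2).any(axis=(1, 3))
    n = int(overlap.sum())
    if n == 0:
        return {f: float("nan") for f in WAVELET_FEATURES}
    return {
        "WavEnLL": float((ll[overlap] ** 2).mean()),
        "WavEnLH": float((lh[overlap] ** 2).mean()),
        "WavEnHL": float((hl[overlap] ** 2).mean()),
        "WavEnHH": float((hh[overlap] ** 2).mean()),
    }
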