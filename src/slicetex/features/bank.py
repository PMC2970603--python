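"""Assembly of the full 264-parameter feature vector for one ROI."""

from __future__ import annotations

import pandas as pd

from ..roi import QuantizedRoi
from .ar import ar_features
from .firstorder import gradient_features, histogram_features
from .glcm import glcm_feature_block
from .names import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    GLCM_FEATURES,
    glcm_name,
    glcm_offsets,
)
from .rlm import rlm_feature_block
from .wavelet import wavelet_features


def extract_all(roi: QuantizedRoi) -> pd.Series:
    """All 264 texture parameters of one ROI, in canonical order.

    Undefined features (degenerate ROI, no valid pixel pair at an offset,
    rank-deficient autoregression, ...) carry NaN as an explicit undefined
    marker; the vector itself is always complete and deterministic.
    """
    values: dict[str, float] = {}
    values.update(histogram_features(roi.clipped))
    values.update(gradient_features(roi))
    values.update(glcm_feature_block(roi))
    values.update(rlm_feature_block(roi))
    values.update(wavelet_features(roi))
    values.update(ar_features(roi))
    vec = pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES),
                    dtype=float)
    return vec


def feature_dictionary() -> pd.DataFrame:
    """One row per feature: name, family, and offset/direction where applicable."""
    rows = []
    offset_of = {}
    for dx, dy in glcm_offsets():
        for f in GLCM_FEATURES:
            offset_of[glcm_name(dx, dy, f)] = f"(dx={dx}, dy={dy})"
    for name in FEATURE_NAMES:
        group = FEATURE_GROUPS[name]
        detail = offset_of.get(name, "")
        if group == "rlm":
            detail = {"Horzl": "0 deg", "Vertl": "90 deg", "45dgr": "45 deg",
                      "135dr": "135 deg"}[name.split("_")[0]]
        rows.append({"feature": name, "group": group, "detail": detail})
    return pd.DataFrame(rows)
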