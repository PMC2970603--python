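"""Shared fixtures: random ROI factory, small and full-size phantom cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import slicetex as st
from slicetex.roi import QuantizedRoi, RawRoi, RoiMask, normalize_quantize

# fixed study-conditions seed for the full-size phantom run
STUDY_SEED = 20100


def random_quantized_roi(
    rng: np.random.Generator,
    shape=(10, 10),
    n_levels: int = 8,
    irregular: bool = True,
) -> QuantizedRoi:
    """A random ROI with integer intensities, optionally with holes/irregular support."""
    h, w = shape
    mask = np.ones(shape, dtype=bool)
    if irregular:
        while True:
            mask = rng.random(shape) > 0.25
            if mask.sum() >= max(8, h * w // 3):
                break
    values = rng.integers(0, 200, size=shape)
    rows, cols = np.nonzero(mask)
    roi_mask = RoiMask(rows=rows, cols=cols, kind="WM")
    raw = RawRoi(values=values[rows, cols].astype(np.float64), mask=roi_mask)
    return normalize_quantize(raw, n_levels=n_levels)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for structural tests (4 subjects, 64x64 slices)."""
    spec = st.CohortSpec(
        n_subjects=4, slice_shape=(64, 64), msi_size_range=(39, 300), seed=7
    )
    return st.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return st.build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def study_table():
    """Feature table of the full-size default phantom (the study conditions)."""
    cohort = st.generate_cohort(st.CohortSpec(seed=STUDY_SEED))
    return st.build_feature_table(cohort)
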