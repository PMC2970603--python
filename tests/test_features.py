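"""The 264-parameter texture bank: cardinalities, analytic toys, brute-force
oracle equivalence, and the directional/affine invariances."""

import numpy as np
import pandas as pd
import pytest

import slicetex as st
from slicetex.features import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    GLCM_FEATURES,
    GROUP_SIZES,
    N_FEATURES,
    ar_features,
    cooccurrence_matrix,
    extract_all,
    glcm_name,
    glcm_offsets,
    gradient_features,
    haralick_features,
    histogram_features,
    rlm_features_direction,
    wavelet_features,
)
from slicetex.roi import QuantizedRoi, RawRoi, RoiMask, normalize_quantize

from .oracles import (
    glcm_matrix_bruteforce,
    gradient_values_bruteforce,
    haralick_bruteforce,
    histogram_bruteforce,
    rlm_bruteforce,
    wavelet_bruteforce,
)
from .conftest import random_quantized_roi


def roi_from_levels(levels, n_levels):
    """A QuantizedRoi with prescribed integer levels (clipped = levels)."""
    levels = np.asarray(levels)
    mask = RoiMask.from_rect(0, 0, *levels.shape, kind="WM")
    flat = levels.ravel()
    return QuantizedRoi(
        levels=flat.astype(np.int64), n_levels=n_levels, mu=float(flat.mean()),
        sigma=float(flat.std()), clipped=flat.astype(float), mask=mask,
    )


def levels_dict(roi: QuantizedRoi) -> dict:
    return {
        (int(r), int(c)): int(g)
        for r, c, g in zip(roi.mask.rows, roi.mask.cols, roi.levels)
    }


def values_dict(roi: QuantizedRoi) -> dict:
    return {
        (int(r), int(c)): float(v)
        for r, c, v in zip(roi.mask.rows, roi.mask.cols, roi.clipped)
    }


class TestCardinalities:
    def test_bank_composition(self):
        assert len(FEATURE_NAMES) == N_FEATURES == 264
        counts = pd.Series(FEATURE_GROUPS).value_counts().to_dict()
        assert counts == GROUP_SIZES
        assert GROUP_SIZES == {
            "histogram": 11, "gradient": 4, "glcm": 220, "rlm": 20,
            "wavelet": 4, "ar": 5,
        }

    def test_extract_all_complete_and_deterministic(self, rng):
        roi = random_quantized_roi(rng, shape=(12, 12), n_levels=16)
        v1, v2 = extract_all(roi), extract_all(roi)
        assert list(v1.index) == list(FEATURE_NAMES)
        pd.testing.assert_series_equal(v1, v2)


class TestGlcmAnalytic:
    def test_2x2_hand_example(self):
        """[[1,2],[1,2]] at offset (1,0): p(1,2) = p(2,1) = 1/2."""
        roi = roi_from_levels([[1, 2], [1, 2]], n_levels=2)
        p = cooccurrence_matrix(roi, (1, 0))
        np.testing.assert_allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        f = haralick_features(p)
        assert f["AngScMom"] == pytest.approx(0.5)
        assert f["Contrast"] == pytest.approx(1.0)

    def test_single_level_matrix(self):
        roi = roi_from_levels([[3, 3], [3, 3]], n_levels=4)
        f = haralick_features(cooccurrence_matrix(roi, (1, 0)))
        assert f["Contrast"] == 0.0
        assert f["AngScMom"] == 1.0
        assert f["Entropy"] == 0.0
        assert np.isnan(f["Correlat"])  # zero marginal variance

    def test_matrix_normalised(self, rng):
        roi = random_quantized_roi(rng, shape=(9, 9), n_levels=6)
        for off in glcm_offsets():
            p = cooccurrence_matrix(roi, off)
            if p is not None:
                assert p.sum() == pytest.approx(1.0)
                np.testing.assert_allclose(p, p.T)

    def test_transpose_swaps_0_and_90_degrees(self, rng):
        for _ in range(10):
            lv = rng.integers(1, 6, (8, 8))
            transposed = roi_from_levels(lv.T, 5)
            full = roi_from_levels(lv, 5)
            for d in (1, 2):
                a = cooccurrence_matrix(full, (d, 0))
                b = cooccurrence_matrix(transposed, (0, d))
                np.testing.assert_allclose(a, b)

    def test_no_valid_pairs_gives_undefined(self):
        roi = roi_from_levels([[1, 2]], n_levels=2)  # 1x2: no pair at distance 5
        assert cooccurrence_matrix(roi, (5, 0)) is None
        vec = extract_all(roi)
        assert np.isnan(vec[glcm_name(5, 0, "Contrast")])


class TestRlmAnalytic:
    def test_single_row_hand_example(self):
        """[1,1,2,2,2]: runs (1,len 2),(2,len 3); ShrtREmph = (1/4+1/9)/2."""
        roi = roi_from_levels([[1, 1, 2, 2, 2]], n_levels=2)
        f = rlm_features_direction(roi, "Horzl")
        assert f["ShrtREmph"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["LngREmph"] == pytest.approx((4 + 9) / 2)

    def test_constant_square_fraction(self):
        n = 6
        roi = roi_from_levels(np.full((n, n), 2), n_levels=4)
        f = rlm_features_direction(roi, "Horzl")
        assert f["Fraction"] == pytest.approx(1 / n)
        assert f["LngREmph"] == pytest.approx(n ** 2)


class TestOracleEquivalence:
    """Every feature family against an independent brute-force implementation."""

    N_ROIS = 50

    def _rois(self, rng):
        for i in range(self.N_ROIS):
            yield random_quantized_roi(
                rng, shape=(10, 10), n_levels=8, irregular=(i % 2 == 0)
            )

    def test_glcm_all_offsets(self, rng):
        for roi in self._rois(rng):
            ld = levels_dict(roi)
            for off in glcm_offsets():
                p = cooccurrence_matrix(roi, off)
                p_ref = glcm_matrix_bruteforce(ld, off, roi.n_levels)
                if p is None:
                    assert p_ref is None
                    continue
                np.testing.assert_allclose(p, p_ref, rtol=1e-10, atol=1e-14)
                f, f_ref = haralick_features(p), haralick_bruteforce(p_ref)
                for name in GLCM_FEATURES:
                    np.testing.assert_allclose(
                        f[name], f_ref[name], rtol=1e-10, atol=1e-12, err_msg=name
                    )

    def test_rlm_all_directions(self, rng):
        for roi in self._rois(rng):
            ld = levels_dict(roi)
            for d in ("Horzl", "Vertl", "45dgr", "135dr"):
                f = rlm_features_direction(roi, d)
                f_ref = rlm_bruteforce(ld, d, roi.n_pixels)
                for name, v in f.items():
                    np.testing.assert_allclose(
                        v, f_ref[name], rtol=1e-10, atol=1e-12, err_msg=f"{d}_{name}"
                    )

    def test_histogram(self, rng):
        for roi in self._rois(rng):
            f = histogram_features(roi.clipped)
            f_ref = histogram_bruteforce(roi.clipped)
            for name, v in f.items():
                np.testing.assert_allclose(v, f_ref[name], rtol=1e-10, err_msg=name)

    def test_gradient(self, rng):
        for roi in self._rois(rng):
            g_ref = gradient_values_bruteforce(values_dict(roi))
            f = gradient_features(roi)
            if not g_ref:
                assert all(np.isnan(v) for v in f.values())
                continue
            f_ref = histogram_bruteforce(g_ref)
            np.testing.assert_allclose(f["GrMean"], f_ref["Mean"], rtol=1e-10)
            np.testing.assert_allclose(f["GrVariance"], f_ref["Variance"], rtol=1e-10,
                                       atol=1e-12)

    def test_wavelet(self, rng):
        for roi in self._rois(rng):
            v, m = roi.value_image()
            mean = float(roi.clipped.mean())
            img = np.where(m, v, mean)
            if img.shape[0] % 2:
                img = np.vstack([img, np.full((1, img.shape[1]), mean)])
                m = np.vstack([m, np.zeros((1, m.shape[1]), dtype=bool)])
            if img.shape[1] % 2:
                img = np.hstack([img, np.full((img.shape[0], 1), mean)])
                m = np.hstack([m, np.zeros((m.shape[0], 1), dtype=bool)])
            f = wavelet_features(roi)
            f_ref = wavelet_bruteforce(img, m)
            for name, val in f.items():
                np.testing.assert_allclose(val, f_ref[name], rtol=1e-10, atol=1e-12,
                                           err_msg=name)


class TestGradientAnalytic:
    def test_constant_roi_zero_gradient(self):
        roi = roi_from_levels(np.full((6, 6), 5), n_levels=8)
        f = gradient_features(roi)
        assert f["GrMean"] == 0.0 and f["GrVariance"] == 0.0

    def test_vertical_ramp_recovers_slope(self):
        ramp = np.tile(np.arange(8)[:, None], (1, 8)) * 3
        roi = roi_from_levels(ramp, n_levels=32)
        f = gradient_features(roi)
        assert f["GrMean"] == pytest.approx(3.0)
        assert f["GrVariance"] == pytest.approx(0.0, abs=1e-12)


class TestWaveletAnalytic:
    def test_constant_roi(self):
        roi = roi_from_levels(np.full((8, 8), 4), n_levels=8)
        f = wavelet_features(roi)
        assert f["WavEnLH"] == f["WavEnHL"] == f["WavEnHH"] == 0.0
        assert f["WavEnLL"] > 0.0

    def test_checkerboard_peaks_in_hh(self):
        i, j = np.mgrid[0:8, 0:8]
        board = ((i + j) % 2) * 10 + 1
        f = wavelet_features(roi_from_levels(board, n_levels=16))
        assert f["WavEnHH"] > f["WavEnLH"]
        assert f["WavEnHH"] > f["WavEnHL"]
        assert f["WavEnHH"] > 0.0


class TestArFeatures:
    def test_white_noise_thetas_near_zero(self, rng):
        x = rng.normal(100, 10, (48, 48))
        mask = RoiMask.from_rect(0, 0, 48, 48, "WM")
        raw = RawRoi(x[mask.rows, mask.cols], mask)
        f = ar_features(normalize_quantize(raw))
        n = 47 * 46
        se = 3.0 / np.sqrt(n)  # ~3 standard errors of an OLS slope on white noise
        for k in range(1, 5):
            assert abs(f[f"Teta{k}"]) < se
        assert f["Sigma"] == pytest.approx(10.0, rel=0.1)

    def test_parameter_recovery(self):
        theta = (0.3, 0.1, 0.3, 0.1)
        d = st.TissueTextureDescriptor(600.0, 30.0, 1.0, ar_coefficients=theta)
        field = st.synthesize_texture(d, (64, 64), 0)
        mask = RoiMask.from_rect(0, 0, 64, 64, "WM")
        raw = RawRoi(field[mask.rows, mask.cols], mask)
        f = ar_features(normalize_quantize(raw))
        for k in range(4):
            assert f[f"Teta{k + 1}"] == pytest.approx(theta[k], abs=0.05)

    def test_exact_solution_on_small_system(self):
        """On a small grid the fit must equal the directly solved least-squares
        system assembled by hand from the causal neighbourhoods."""
        img = np.array(
            [
                [3, 1, 4, 1, 5],
                [9, 2, 6, 5, 3],
                [5, 8, 9, 7, 9],
            ],
            dtype=float,
        )
        roi = roi_from_levels(img.astype(int), n_levels=16)
        f = ar_features(roi, min_pixels=1)
        xc = img - img.mean()
        rows, ys = [], []
        for r in (1, 2):
            for c in (1, 2, 3):
                rows.append(
                    [xc[r, c - 1], xc[r - 1, c - 1], xc[r - 1, c], xc[r - 1, c + 1]]
                )
                ys.append(xc[r, c])
        sol, *_ = np.linalg.lstsq(np.array(rows), np.array(ys), rcond=None)
        resid = np.array(ys) - np.array(rows) @ sol
        for k in range(4):
            assert f[f"Teta{k + 1}"] == pytest.approx(sol[k], abs=1e-9)
        assert f["Sigma"] == pytest.approx(np.sqrt((resid ** 2).mean()), abs=1e-9)

    def test_constant_roi_undefined(self):
        roi = roi_from_levels(np.full((10, 10), 3), n_levels=8)
        f = ar_features(roi)
        assert all(np.isnan(v) for v in f.values())


class TestInvariances:
    def test_affine_intensity_invariance_of_glcm_rlm(self, rng):
        """Second-order features are exactly invariant to x -> a*x + b via the
        per-ROI normalization (up to floor-boundary ties, avoided here by
        integer-friendly transforms)."""
        img = rng.integers(0, 300, (12, 12))
        mask = RoiMask.from_rect(0, 0, 12, 12, "WM")
        q1 = normalize_quantize(RawRoi(img[mask.rows, mask.cols].astype(float), mask), 16)
        q2 = normalize_quantize(
            RawRoi((2 * img[mask.rows, mask.cols] + 100).astype(float), mask), 16
        )
        np.testing.assert_array_equal(q1.levels, q2.levels)
        v1, v2 = extract_all(q1), extract_all(q2)
        glcm_rlm = [n for n in FEATURE_NAMES if FEATURE_GROUPS[n] in ("glcm", "rlm")]
        pd.testing.assert_series_equal(v1[glcm_rlm], v2[glcm_rlm])

    def test_rotation_permutes_directional_features(self, rng):
        """Rotating the ROI 90 deg swaps 0<->90 and 45<->135 degree features."""
        img = rng.integers(1, 9, (10, 10))
        base = roi_from_levels(img, n_levels=8)
        rot = roi_from_levels(np.rot90(img), n_levels=8)
        v_base, v_rot = extract_all(base), extract_all(rot)
        swap = {(1, 0): (0, 1), (0, 1): (1, 0), (1, 1): (1, -1), (1, -1): (1, 1)}
        for d in (1, 2, 3):
            for (ax, ay), (bx, by) in swap.items():
                for f in GLCM_FEATURES:
                    a = v_base[glcm_name(d * ax, d * ay, f)]
                    b = v_rot[glcm_name(d * bx, d * by, f)]
                    np.testing.assert_allclose(a, b, rtol=1e-12, err_msg=f)
        for fa, fb in (("Horzl", "Vertl"), ("45dgr", "135dr")):
            for f in ("ShrtREmph", "LngREmph", "Fraction"):
                np.testing.assert_allclose(
                    v_base[f"{fa}_{f}"], v_rot[f"{fb}_{f}"], rtol=1e-12
                )
                np.testing.assert_allclose(
                    v_base[f"{fb}_{f}"], v_rot[f"{fa}_{f}"], rtol=1e-12
                )

    def test_degenerate_roi_markers_not_zero(self):
        roi_raw = RawRoi(np.full(100, 7.0), RoiMask.from_rect(0, 0, 10, 10, "WM"))
        vec = extract_all(normalize_quantize(roi_raw, 64))
        assert vec["Mean"] == 7.0 and vec["Variance"] == 0.0
        assert np.isnan(vec["Skewness"])
        glcm_cols = [n for n in FEATURE_NAMES if FEATURE_GROUPS[n] == "glcm"]
        assert vec[glcm_cols].isna().all()
        assert np.isnan(vec["Teta1"])
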