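"""Wilcoxon signed-ranks test, separability screening and Fisher ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import slicetex as st
from slicetex.stats import fisher_rank, separability, wilcoxon_signed_rank

from .oracles import wilcoxon_exact_bruteforce


class TestWilcoxon:
    def test_all_positive_five(self):
        """[1,2,3,4,5]: W+ maximal, exact two-sided p = 2/32."""
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(0.0625)
        assert res.exact

    def test_antisymmetric_pair(self):
        assert wilcoxon_signed_rank([-1, 1]).p_value == 1.0

    def test_all_zero_flag(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.all_zero

    def test_exact_matches_full_enumeration(self, rng):
        """200 random difference vectors (n <= 10, with ties and zeros)."""
        for _ in range(200):
            n = int(rng.integers(1, 11))
            d = rng.integers(-4, 5, n).astype(float)
            if (d == 0).all():
                continue
            p = wilcoxon_signed_rank(d).p_value
            p_ref = wilcoxon_exact_bruteforce(d)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 26))
            d = rng.normal(0.3, 1.0, n)  # continuous: no ties, no zeros
            p = wilcoxon_signed_rank(d).p_value
            p_ref = sps.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_large_n_approximation_close_to_scipy(self, rng):
        d = rng.normal(0.4, 1.0, 60)
        p = wilcoxon_signed_rank(d).p_value
        p_ref = sps.wilcoxon(d, method="approx", correction=True).pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)


class TestFisher:
    def test_hand_example(self):
        """Classes {0,2} and {4,6}: D = 4, V = 1, F = 4."""
        df = pd.DataFrame({"f": [0.0, 2.0, 4.0, 6.0]})
        r = fisher_rank(df, ["a", "a", "b", "b"])
        assert r.f_values["f"] == pytest.approx(4.0)

    def test_identical_classes_zero(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]})
        r = fisher_rank(df, ["a", "a", "b", "b"])
        assert r.f_values["f"] == 0.0

    def test_affine_invariance_and_label_swap(self, rng):
        x = rng.normal(0, 1, 40)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        x[20:] += 1.5
        df = pd.DataFrame({"f": x, "g": -3.0 * x + 7.0})
        r = fisher_rank(df, labels)
        assert r.f_values["f"] == pytest.approx(r.f_values["g"], rel=1e-12)
        r_swapped = fisher_rank(df, np.where(labels == "a", "b", "a"))
        assert r.f_values["f"] == pytest.approx(r_swapped.f_values["f"], rel=1e-12)

    def test_zero_within_variance_ranks_first(self):
        df = pd.DataFrame({
            "noisy": [0.0, 1.0, 5.0, 6.0],
            "perfect": [1.0, 1.0, 2.0, 2.0],   # V = 0, D > 0 -> +inf
            "flat": [3.0, 3.0, 3.0, 3.0],      # V = D = 0 -> excluded
            "undef": [1.0, np.nan, 2.0, 3.0],  # undefined -> excluded
        })
        r = fisher_rank(df, ["a", "a", "b", "b"])
        assert r.top_k[0] == "perfect"
        assert np.isinf(r.f_values["perfect"])
        assert set(r.excluded) == {"flat", "undef"}

    def test_small_class_rejected(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fisher_rank(df, ["a", "b", "b"])

    def test_tie_break_lexicographic(self):
        df = pd.DataFrame({"b_feat": [0, 0, 1, 1.0], "a_feat": [0, 0, 1, 1.0],
                           "c_feat": [0.0, 1.0, 2.0, 3.0]})
        r = fisher_rank(df, ["x", "x", "y", "y"], top_k=2)
        assert r.top_k == ["a_feat", "b_feat"]


def _toy_table(rng, n_subjects=12, shift=0.0, features=("f1", "f2", "f3")):
    rows = []
    for s in range(n_subjects):
        for lev in (0, 1):
            for kind in ("WM", "NAWM"):
                base = rng.normal(0, 1, len(features))
                if kind == "NAWM":
                    base = base + shift
                row = {"subject": s, "level": lev, "sequence": "T1",
                       "thickness": "1mm", "roi_kind": kind}
                row.update({f: v for f, v in zip(features, base)})
                rows.append(row)
    return pd.DataFrame(rows)


class TestSeparability:
    def test_table_vs_itself_is_never_significant(self, rng):
        tab = _toy_table(rng)
        rep = separability(
            tab,
            {"roi_kind": "WM"},
            {"roi_kind": "WM"},
            feature_columns=["f1", "f2", "f3"],
        )
        assert rep.percent_significant == 0.0
        assert (rep.p_values == 1.0).all()

    def test_strong_shift_all_significant(self, rng):
        tab = _toy_table(rng, shift=5.0)
        rep = separability(
            tab, {"roi_kind": "WM"}, {"roi_kind": "NAWM"},
            feature_columns=["f1", "f2", "f3"],
        )
        assert rep.percent_significant == 100.0
        assert rep.n_pairs == 24

    def test_missing_pairing_unit_dropped_with_warning(self, rng):
        tab = _toy_table(rng)
        tab = tab[~((tab.subject == 0) & (tab.level == 1) & (tab.roi_kind == "NAWM"))]
        with pytest.warns(UserWarning, match="excluded"):
            rep = separability(
                tab, {"roi_kind": "WM"}, {"roi_kind": "NAWM"},
                feature_columns=["f1"],
            )
        assert rep.n_pairs == 23
        assert rep.dropped_units == [(0, 1)]

    def test_undefined_features_excluded_pairwise(self, rng):
        tab = _toy_table(rng)
        tab.loc[tab.roi_kind == "NAWM", "f3"] = np.nan
        rep = separability(
            tab, {"roi_kind": "WM"}, {"roi_kind": "NAWM"},
            feature_columns=["f1", "f2", "f3"],
        )
        assert rep.n_excluded_features == 1
        assert np.isnan(rep.p_values["f3"])
        assert rep.n_tested == 2

    def test_null_type_one_rate_calibrated(self, rng):
        """Independent null features: share of p < 0.05 within the binomial
        99% band around the nominal level."""
        m = 400
        feats = [f"f{i}" for i in range(m)]
        tab = _toy_table(rng, n_subjects=20, features=feats)
        rep = separability(tab, {"roi_kind": "WM"}, {"roi_kind": "NAWM"},
                           feature_columns=feats)
        from scipy.stats import binom

        lo = binom.ppf(0.005, m, 0.05) / m * 100
        hi = binom.ppf(0.995, m, 0.05) / m * 100
        assert lo <= rep.percent_significant <= hi
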