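"""FPKM, replicate correlation, BH adjustment and the NB exact test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stresslnc.expression import (
    bh_adjust,
    compute_fpkm,
    estimate_common_dispersion,
    exact_test_de,
    exact_test_pvalue,
    replicate_correlation,
)
from stresslnc.synthetic import simulate_count_matrix


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"S1": [100, 0]}, index=["a", "b"])
        fpkm = compute_fpkm(counts, {"S1": 1_000_000}, {"a": 1000, "b": 500})
        assert fpkm.at["a", "S1"] == pytest.approx(100.0)
        assert fpkm.at["b", "S1"] == 0.0

    @pytest.mark.parametrize("lib,lens", [(0, 1000), (1_000_000, 0)])
    def test_zero_denominators_rejected(self, lib, lens):
        counts = pd.DataFrame({"S1": [1]}, index=["a"])
        with pytest.raises(ValueError):
            compute_fpkm(counts, {"S1": lib}, {"a": lens})


class TestReplicateCorrelation:
    def test_identical_replicates_give_r2_one(self):
        f = pd.DataFrame({"PC1": [1, 5, 9.0], "PC2": [1, 5, 9.0]})
        table, mn = replicate_correlation(f, ["PC1", "PC2"])
        assert mn == pytest.approx(1.0)

    def test_sign_is_lost_by_squaring(self):
        # after log2(x+1), choose vectors with perfectly negative correlation
        x = np.array([1.0, 2.0, 3.0])
        y = 4.0 - x  # log-space anticorrelation is not exact; build in log space
        f = pd.DataFrame({"A": 2**x - 1, "B": 2**y - 1})
        table, mn = replicate_correlation(f, ["A", "B"])
        assert mn == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(7)
        f = pd.DataFrame(rng.gamma(2, 50, size=(1000, 2)), columns=["A", "B"])
        table, _ = replicate_correlation(f, ["A", "B"])
        x, y = np.log2(f["A"] + 1), np.log2(f["B"] + 1)
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert table.loc["A", "B"] == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_zero_variance_replicate_warns_and_is_nan(self):
        f = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero variance"):
            table, _ = replicate_correlation(f, ["A", "B"])
        assert np.isnan(table.loc["A", "B"])


class TestBhAdjust:
    def test_hand_enumerated_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert bh_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_dominates_p(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestExactTest:
    def test_equal_counts_give_p_one_and_zero_lfc(self):
        counts = pd.DataFrame(
            [[10, 10, 10, 10, 10, 10]], index=["f"],
            columns=["PC1", "PC2", "PC3", "PH1", "PH2", "PH3"],
        )
        cond = pd.Series({"PC1": "control", "PC2": "control", "PC3": "control",
                          "PH1": "heat", "PH2": "heat", "PH3": "heat"})
        res = exact_test_de(counts, cond, dispersion=0.1)
        assert res.at["f", "pvalue"] == pytest.approx(1.0)
        assert res.at["f", "log2fc"] == pytest.approx(0.0)
        assert res.at["f", "de_flag"] == "ns"

    def test_binomial_limit_enumeration_example(self):
        # 0 vs 10 with phi=0 and equal groups: Binomial(10, 1/2) two-sided
        assert exact_test_pvalue(0, 10, 3, 3, 0.0) == pytest.approx(2 / 1024, abs=1e-12)

    def test_binomial_limit_matches_scipy_on_random_features(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            total = int(rng.integers(1, 500))
            sa = int(rng.integers(0, total + 1))
            p_ours = exact_test_pvalue(sa, total - sa, 3, 3, 0.0)
            p_ref = stats.binomtest(sa, total, 0.5).pvalue
            assert p_ours == pytest.approx(p_ref, abs=1e-9)

    def test_unbalanced_groups_binomial_limit(self):
        p_ours = exact_test_pvalue(3, 17, 2, 4, 0.0)
        p_ref = stats.binomtest(3, 20, 2 / 6).pvalue
        assert p_ours == pytest.approx(p_ref, abs=1e-9)

    def test_all_zero_feature_is_ns(self):
        counts = pd.DataFrame(
            [[0] * 6, [50, 60, 55, 200, 210, 190]], index=["z", "f"],
            columns=["PC1", "PC2", "PC3", "PH1", "PH2", "PH3"],
        )
        cond = pd.Series({c: ("control" if c.startswith("PC") else "heat")
                          for c in counts.columns})
        res = exact_test_de(counts, cond, dispersion=0.05)
        assert res.at["z", "pvalue"] == 1.0
        assert res.at["z", "log2fc"] == 0.0
        assert res.at["z", "de_flag"] == "ns"

    def test_label_swap_negates_lfc_and_keeps_p(self):
        counts, cond, _ = simulate_count_matrix(50, seed=9, dispersion=0.1)
        res = exact_test_de(counts, cond, dispersion=0.1)
        swapped = cond.map({"control": "heat", "heat": "control"})
        res2 = exact_test_de(counts, swapped, dispersion=0.1)
        assert np.allclose(res["pvalue"], res2["pvalue"], atol=1e-12)
        nz = counts.sum(axis=1) > 0
        assert np.allclose(res.loc[nz, "log2fc"], -res2.loc[nz, "log2fc"], atol=1e-12)

    def test_flag_rule_uses_padj_and_lfc_thresholds(self):
        counts, cond, truth = simulate_count_matrix(
            300, mean_low=50, mean_high=500, dispersion=0.05,
            frac_de=0.3, log2fc=2.5, seed=12,
        )
        res = exact_test_de(counts, cond)
        sig = res[res["de_flag"] != "ns"]
        assert ((sig["padj"] <= 0.05) & (sig["log2fc"].abs() >= 1)).all()
        ns = res[res["de_flag"] == "ns"]
        assert ((ns["padj"] > 0.05) | (ns["log2fc"].abs() < 1)).all()
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()

    def test_dispersion_estimator_recovers_truth(self):
        counts, cond, _ = simulate_count_matrix(
            3000, mean_low=50, mean_high=500, dispersion=0.1, seed=3
        )
        phi = estimate_common_dispersion(counts, cond)
        assert 0.07 < phi < 0.13

    def test_dispersion_ignores_between_condition_signal(self):
        counts, cond, _ = simulate_count_matrix(
            2000, mean_low=100, mean_high=100, dispersion=0.0,
            frac_de=0.5, log2fc=3.0, seed=4,
        )
        phi = estimate_common_dispersion(counts, cond)
        assert phi < 0.02  # pooled within conditions, effects excluded
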