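import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autoscore.diff import (
    LAYER_SPECS,
    DifferentialFeatureCaller,
    LayerSpec,
    bh_fdr,
    binary_feature_test,
    call_significant_features,
    continuous_feature_test,
    exact_binary_p,
    pathway_protein_score,
    permutation_stability,
    sign_magnitude_fc,
    summarize_counts,
    analyze_layer,
    weighted_group_stats,
)
from _oracles import naive_bh


def _groups(n_high, n_low):
    return pd.Series(["high"] * n_high + ["low"] * n_low)


class TestWeightedGroupStats:
    def test_unit_weights_recover_plain_stats(self, rng):
        x = rng.normal(size=40)
        g = _groups(20, 20)
        mh, ml, vh, vl, eh, el = weighted_group_stats(x, g)
        np.testing.assert_allclose(mh, x[:20].mean())
        np.testing.assert_allclose(vl, x[20:].var(ddof=1))
        assert eh == pytest.approx(20) and el == pytest.approx(20)

    def test_duplicate_equals_weight_two(self, rng):
        x = rng.normal(size=10)
        g = _groups(5, 5)
        x_dup = np.concatenate([x, [x[0]]])
        g_dup = pd.Series(list(g) + ["high"])
        w = np.ones(10)
        w[0] = 2.0
        mh_dup, *_ = weighted_group_stats(x_dup, g_dup)
        mh_w, *_ = weighted_group_stats(x, g, w)
        assert mh_dup == pytest.approx(mh_w)

    def test_ess_bounded_by_n(self, rng):
        x = rng.normal(size=100)
        g = _groups(50, 50)
        w = rng.uniform(0.1, 1.0, size=100)
        *_, eh, el = weighted_group_stats(x, g, w)
        assert eh <= 50 + 1e-9 and el <= 50 + 1e-9

    def test_zero_total_weight_errors(self):
        with pytest.raises(ValueError, match="weight"):
            weighted_group_stats(np.ones(4), _groups(2, 2), np.array([0.0, 0.0, 1.0, 1.0]))


class TestSignMagnitudeConvention:
    @pytest.mark.parametrize(
        "mh,ml,expected",
        [(2.0, 1.0, 2.0), (1.0, 2.0, -2.0), (1.0, 1.0, 1.0), (3.0, 2.0, 1.5), (2.0, 3.0, -1.5)],
    )
    def test_fold_change_examples(self, mh, ml, expected):
        assert sign_magnitude_fc(np.array([mh]), np.array([ml]))[0] == pytest.approx(expected)

    def test_identical_groups_effect_one_p_near_one(self, rng):
        x = np.tile(rng.normal(5, 1, size=30), 2)
        g = _groups(30, 30)
        out = continuous_feature_test(x, g, spec=LAYER_SPECS["mRNA"])
        assert out["effect"] == pytest.approx(1.0)
        assert out["p_value"] > 0.99

    def test_zero_denominator_signed_infinity(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        g = _groups(2, 2)
        out = continuous_feature_test(x, g, spec=LAYER_SPECS["mRNA"])
        assert out["effect"] == np.inf


class TestContinuousPower:
    def test_planted_fc3_detected(self, rng):
        detected = 0
        reps = 100
        for _ in range(reps):
            low = rng.normal(10, 5, size=100)
            high = rng.normal(30, 15, size=100)
            x = np.concatenate([high, low])
            out = continuous_feature_test(x, _groups(100, 100), spec=LAYER_SPECS["mRNA"])
            detected += out["p_value"] < 0.05
        assert detected >= 99

    def test_label_swap_negates_effect_keeps_p(self, rng):
        x = rng.normal(10, 2, size=60)
        g = _groups(30, 30)
        g_swapped = pd.Series(np.where(g == "high", "low", "high"))
        a = continuous_feature_test(x, g, spec=LAYER_SPECS["mRNA"])
        b = continuous_feature_test(x, g_swapped, spec=LAYER_SPECS["mRNA"])
        assert a["effect"] == pytest.approx(-b["effect"])
        assert a["p_value"] == pytest.approx(b["p_value"])


class TestBinaryTest:
    def test_equal_proportions_null(self):
        x = np.array([1, 0] * 20, dtype=float)
        out = binary_feature_test(x, _groups(20, 20))
        assert out["effect"] == pytest.approx(0.0)
        assert out["p_value"] > 0.9

    def test_exact_p_matches_fisher_20_of_100_vs_5_of_100(self):
        got = exact_binary_p(20, 100, 5, 100)
        _, fisher_p = stats.fisher_exact([[20, 5], [80, 95]], alternative="two-sided")
        assert got == pytest.approx(fisher_p, rel=1e-9)

    def test_sparse_table_triggers_exact_path(self):
        # 4/30 vs 0/30: expected positive cells are 2 < 5 -> exact test
        x = np.concatenate([np.ones(4), np.zeros(26), np.zeros(30)])
        out = binary_feature_test(x, _groups(30, 30))
        _, fisher_p = stats.fisher_exact([[4, 0], [26, 30]], alternative="two-sided")
        assert out["p_value"] == pytest.approx(fisher_p, rel=1e-9)

    def test_exact_matches_enumeration_random_tables(self, rng):
        for _ in range(20):
            nh, nl = int(rng.integers(5, 15)), int(rng.integers(5, 15))
            kh, kl = int(rng.integers(0, nh + 1)), int(rng.integers(0, nl + 1))
            if (kh + kl) in (0, nh + nl):
                continue
            got = exact_binary_p(kh, nh, kl, nl)
            _, expected = stats.fisher_exact(
                [[kh, kl], [nh - kh, nl - kl]], alternative="two-sided"
            )
            assert got == pytest.approx(expected, rel=1e-9)

    def test_constant_feature_uninformative(self):
        out = binary_feature_test(np.zeros(40), _groups(20, 20))
        assert out["p_value"] == 1.0 and out["effect"] == 0.0

    def test_planted_odds_ratio_detected(self, rng):
        hits = 0
        reps = 50
        for _ in range(reps):
            p_low = 0.10
            odds_high = 4 * p_low / (1 - p_low)
            p_high = odds_high / (1 + odds_high)
            x = np.concatenate([
                (rng.random(150) < p_high).astype(float),
                (rng.random(150) < p_low).astype(float),
            ])
            out = binary_feature_test(x, _groups(150, 150))
            hits += out["p_value"] < 0.05
        assert hits >= int(0.9 * reps)


class TestBhFdr:
    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_bruteforce_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(size=int(rng.integers(1, 40)))
            got = bh_fdr(p)
            np.testing.assert_allclose(got, naive_bh(p), atol=1e-12)
            np.testing.assert_allclose(
                got, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_monotone_in_p(self, rng):
        p = rng.random(100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestPermutationStability:
    @staticmethod
    def _matrix(rng, n_feat=50, n=60, planted=0, fc=4.0):
        X = rng.normal(10, 2, size=(n_feat, n))
        X[:planted, : n // 2] *= fc
        return pd.DataFrame(X, index=[f"f{i}" for i in range(n_feat)],
                            columns=[f"s{i}" for i in range(n)])

    def test_deterministic_given_seed(self, rng):
        m = self._matrix(rng)
        g = pd.Series(["high"] * 30 + ["low"] * 30, index=m.columns)
        p1 = permutation_stability(m, g, n_perm=50, seed=7)
        p2 = permutation_stability(m, g, n_perm=50, seed=7)
        pd.testing.assert_series_equal(p1, p2)

    def test_range_and_minimum(self, rng):
        m = self._matrix(rng, planted=3, n=200)
        g = pd.Series(["high"] * 100 + ["low"] * 100, index=m.columns)
        p = permutation_stability(m, g, n_perm=100, seed=1)
        assert ((p >= 1 / 101) & (p <= 1.0)).all()
        np.testing.assert_allclose(p.iloc[:3], 1 / 101)

    def test_constant_feature_perm_p_one(self):
        m = pd.DataFrame(np.ones((1, 20)), index=["c"], columns=[f"s{i}" for i in range(20)])
        g = pd.Series(["high"] * 10 + ["low"] * 10, index=m.columns)
        p = permutation_stability(m, g, n_perm=30, seed=0)
        assert p["c"] == 1.0

    def test_null_perm_p_approximately_uniform(self, rng):
        m = self._matrix(rng, n_feat=2000, n=60)
        g = pd.Series(["high"] * 30 + ["low"] * 30, index=m.columns)
        p = permutation_stability(m, g, n_perm=100, seed=3)
        frac = (p <= 0.05).mean()
        assert 0.03 <= frac <= 0.07


class TestFullCriterion:
    def test_mrna_threshold_blocks_small_effects(self):
        res = pd.DataFrame(
            {"effect": [1.8, 2.5], "p_value": [1e-4, 1e-4],
             "fdr": [0.001, 0.001], "perm_p": [0.01, 0.01]},
            index=["a", "b"],
        )
        out = call_significant_features(res, LAYER_SPECS["mRNA"])
        assert not out.loc["a", "significant"]
        assert out.loc["b", "significant"]

    def test_mirna_negative_effect_significant(self):
        res = pd.DataFrame(
            {"effect": [-1.6], "p_value": [0.001], "fdr": [0.01], "perm_p": [0.01]},
            index=["m"],
        )
        out = call_significant_features(res, LAYER_SPECS["miRNA"])
        assert out.loc["m", "significant"]

    def test_null_layer_no_calls(self, rng):
        X = pd.DataFrame(rng.normal(10, 3, size=(500, 120)),
                         index=[f"f{i}" for i in range(500)],
                         columns=[f"s{i}" for i in range(120)])
        g = pd.Series(["high"] * 60 + ["low"] * 60, index=X.columns)
        res = analyze_layer(X, g, spec=LAYER_SPECS["mRNA"], n_perm=50, seed=2)
        assert res["significant"].sum() <= 1

    def test_summarize_counts(self):
        res_sig = pd.DataFrame({"effect": [3.0], "p_value": [0.0],
                                "fdr": [0.0], "perm_p": [0.0], "significant": [True]})
        res_null = pd.DataFrame({"effect": [1.0], "p_value": [1.0],
                                 "fdr": [1.0], "perm_p": [1.0], "significant": [False]})
        tab = summarize_counts({"C1": {"mRNA": pd.concat([res_sig, res_null])}})
        row = tab.iloc[0]
        assert row["n_significant"] == 1 and row["n_tested"] == 2
        assert row["pct_significant"] == pytest.approx(50.0)


class TestPathwayProteinScore:
    def test_all_zero_members_score_zero(self):
        m = pd.DataFrame(np.zeros((3, 10)), index=["p1", "p2", "p3"],
                         columns=[f"s{i}" for i in range(10)])
        g = pd.Series(["high"] * 5 + ["low"] * 5, index=m.columns)
        out = pathway_protein_score(m, {"pw": [("p1", 1), ("p2", -1)]}, g)
        assert out.loc["pw", "score_diff"] == pytest.approx(0.0)

    def test_single_positive_member_equals_protein(self, rng):
        vals = rng.normal(size=20)
        m = pd.DataFrame([vals], index=["p1"], columns=[f"s{i}" for i in range(20)])
        g = pd.Series(["high"] * 10 + ["low"] * 10, index=m.columns)
        out = pathway_protein_score(m, {"pw": [("p1", 1)]}, g)
        expected = vals[:10].mean() - vals[10:].mean()
        assert out.loc["pw", "score_diff"] == pytest.approx(expected)

    def test_planted_shift_detected(self, rng):
        n = 200
        prots = [f"p{i}" for i in range(6)]
        m = pd.DataFrame(rng.normal(size=(6, n)), index=prots,
                         columns=[f"s{i}" for i in range(n)])
        g = pd.Series(["high"] * 100 + ["low"] * 100, index=m.columns)
        m.loc[["p0", "p1", "p2"], g == "high"] += 0.5
        pathways = {
            "signal": [("p0", 1), ("p1", 1), ("p2", 1)],
            "null": [("p3", 1), ("p4", 1), ("p5", -1)],
        }
        out = pathway_protein_score(m, pathways, g)
        assert out.loc["signal", "score_diff"] > 0
        assert out.loc["signal", "fdr"] < 0.05
        assert out.loc["null", "fdr"] > 0.05

    def test_missing_members_error(self):
        m = pd.DataFrame(np.ones((1, 4)), index=["p1"], columns=list("abcd"))
        g = pd.Series(["high", "high", "low", "low"], index=list("abcd"))
        with pytest.raises(ValueError, match="no members"):
            pathway_protein_score(m, {"pw": [("absent", 1)]}, g)


class TestCallerEstimator:
    def test_fit_recovers_planted_features(self, rng):
        n_feat, n = 300, 160
        X = rng.normal(10, 5, size=(n_feat, n))
        X[:10, :80] *= 3.0
        frame = pd.DataFrame(X.T, index=[f"s{i}" for i in range(n)],
                             columns=[f"f{i}" for i in range(n_feat)])
        y = ["high"] * 80 + ["low"] * 80
        caller = DifferentialFeatureCaller(layer="mRNA", n_perm=50, seed=4).fit(frame, y)
        called = set(caller.significant_)
        planted = {f"f{i}" for i in range(10)}
        assert len(called & planted) >= 9
        assert len(called - planted) <= 2

    def test_unknown_layer_rejected(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 4)))
        with pytest.raises(ValueError, match="unknown layer"):
            DifferentialFeatureCaller(layer="nope").fit(frame, ["high"] * 5 + ["low"] * 5)
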