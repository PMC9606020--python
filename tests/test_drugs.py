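import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autoscore.drugs import (
    annotate_actionable,
    gene_drug_associations,
    score_drug_associations,
    spearman,
)
from autoscore.simulate import SimConfig, gen_drug_panel
from _oracles import naive_spearman


class TestSpearman:
    def test_perfect_antitone(self):
        rs, p = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rs == pytest.approx(-1.0)
        assert p == pytest.approx(0.0)

    def test_hand_example_with_ties(self):
        rs, _ = spearman([1, 2, 2, 3], [1, 2, 3, 4])
        assert rs == pytest.approx(4.5 / np.sqrt(22.5), abs=1e-9)

    def test_matches_naive_and_scipy(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 10, size=n).astype(float)  # ties likely
            y = rng.normal(size=n)
            rs, p = spearman(x, y)
            assert rs == pytest.approx(naive_spearman(x, y), abs=1e-12)
            ref = stats.spearmanr(x, y)
            assert rs == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_pairwise_complete(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 4.0, 1.0, 8.0, np.nan, 12.0]
        rs, _ = spearman(x, y)
        assert rs == pytest.approx(1.0)

    def test_too_few_pairs_nan(self):
        rs, p = spearman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert np.isnan(rs) and np.isnan(p)

    def test_zero_variance_flagged(self):
        rs, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rs)

    def test_invariant_under_monotone_transform(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        rs1, _ = spearman(x, y)
        rs2, _ = spearman(np.exp(x), y**3)
        assert rs1 == pytest.approx(rs2, abs=1e-12)


class TestGeneDrugAssociations:
    def test_planted_signs_recovered(self):
        cfg = SimConfig(seed=2, n_cell_lines=200)
        panel = gen_drug_panel(cfg)
        assoc = gene_drug_associations(panel["expr"], panel["auc"])
        merged = assoc.merge(
            panel["truth"], left_on=["unit", "drug"], right_on=["gene", "drug"]
        )
        sig = merged[merged["label_x"] != "none"]
        assert (sig["label_x"] == sig["label_y"]).all()
        assert len(sig) >= int(0.9 * len(merged))

    def test_magnitude_gate(self, rng):
        # |rs| below 0.3 is never labeled regardless of fdr
        n = 500
        x = rng.normal(size=n)
        y = 0.2 * x + rng.normal(size=n)  # weak but highly significant
        expr = pd.DataFrame([x], index=["g"], columns=[f"c{i}" for i in range(n)])
        auc = pd.DataFrame([y], index=["d"], columns=[f"c{i}" for i in range(n)])
        assoc = gene_drug_associations(expr, auc, rs_min=0.3)
        row = assoc.iloc[0]
        assert abs(row["rs"]) < 0.3 and row["label"] == "none"

    def test_label_antisymmetry_on_negated_response(self):
        cfg = SimConfig(seed=9, n_cell_lines=150, n_sensitive=5, n_resistant=5, n_null_genes=2)
        panel = gen_drug_panel(cfg)
        a1 = gene_drug_associations(panel["expr"], panel["auc"])
        a2 = gene_drug_associations(panel["expr"], -panel["auc"])
        m = a1.merge(a2, on=["unit", "drug"], suffixes=("_pos", "_neg"))
        np.testing.assert_allclose(m["rs_pos"], -m["rs_neg"], atol=1e-12)
        swapped = m[m["label_pos"] != "none"]
        assert (
            swapped["label_neg"].map({"sensitive": "resistant", "resistant": "sensitive"})
            == swapped["label_pos"]
        ).all()

    def test_insufficient_shared_cell_lines_skipped(self, rng):
        expr = pd.DataFrame([[1.0] * 5], index=["g"], columns=[f"c{i}" for i in range(5)])
        auc = pd.DataFrame([[1.0] * 5], index=["d"], columns=[f"c{i}" for i in range(5)])
        assoc = gene_drug_associations(expr, auc, min_n=10)
        assert assoc.empty


class TestScoreDrugAssociations:
    def test_identical_vectors_resistant(self, rng):
        scores = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
        imputed = pd.DataFrame([scores], index=["d"])
        assoc = score_drug_associations(scores, imputed)
        row = assoc.iloc[0]
        assert row["rs"] == pytest.approx(1.0) and row["label"] == "resistant"

    def test_null_panel_no_labels(self, rng):
        n = 150
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        imputed = pd.DataFrame(
            rng.normal(size=(100, n)),
            index=[f"d{i}" for i in range(100)],
            columns=scores.index,
        )
        assoc = score_drug_associations(scores, imputed)
        assert (assoc["label"] != "none").sum() <= 2

    def test_planted_sensitive_drug_recovered(self, rng):
        hits = 0
        reps = 20
        for seed in range(reps):
            r = np.random.default_rng(seed)
            n = 300
            scores = pd.Series(r.normal(size=n), index=[f"s{i}" for i in range(n)])
            rho = -0.5
            rpears = 2 * np.sin(np.pi * rho / 6)
            resp = rpears * scores.to_numpy() + np.sqrt(1 - rpears**2) * r.normal(size=n)
            imputed = pd.DataFrame(
                np.vstack([resp, r.normal(size=(9, n))]),
                index=[f"d{i}" for i in range(10)],
                columns=scores.index,
            )
            assoc = score_drug_associations(scores, imputed).set_index("drug")
            hits += assoc.loc["d0", "label"] == "sensitive"
        assert hits >= int(0.95 * reps)

    def test_few_paired_samples_skipped(self, rng):
        scores = pd.Series(rng.normal(size=5), index=[f"s{i}" for i in range(5)])
        imputed = pd.DataFrame(rng.normal(size=(3, 5)), index=list("abc"), columns=scores.index)
        assert score_drug_associations(scores, imputed).empty


class TestAnnotateActionable:
    def _assoc(self):
        return pd.DataFrame(
            {"unit": ["g1", "g2", "g3"], "drug": ["d1", "d2", "d3"],
             "rs": [0.5, -0.5, 0.1], "fdr": [0.01, 0.01, 0.9],
             "label": ["resistant", "sensitive", "none"]}
        )

    def test_cag_flag_true_for_targeting_drug(self):
        targets = pd.DataFrame({"drug": ["d1", "d2"], "target": ["CAG1", "OTHER"]})
        out = annotate_actionable(self._assoc(), targets, ["CAG1"])
        assert out.set_index("drug").loc["d1", "targets_cag"]
        assert not out.set_index("drug").loc["d2", "targets_cag"]

    def test_empty_cag_list_all_false(self):
        targets = pd.DataFrame({"drug": ["d1"], "target": ["G"]})
        out = annotate_actionable(self._assoc(), targets, [])
        assert not out["targets_cag"].any()

    def test_unannotated_drug_flagged(self):
        targets = pd.DataFrame({"drug": ["d1"], "target": ["G"]})
        out = annotate_actionable(self._assoc(), targets, ["G"])
        assert not out.set_index("drug").loc["d3", "annotated"]

    def test_flags_equal_bruteforce_join(self, rng):
        drugs = [f"d{i}" for i in range(10)]
        genes = [f"t{i}" for i in range(15)]
        targets = pd.DataFrame(
            {"drug": [drugs[i % 10] for i in range(30)],
             "target": [genes[i % 15] for i in range(30)]}
        ).drop_duplicates()
        cags = set(genes[:4])
        assoc = pd.DataFrame({"unit": ["g"] * 10, "drug": drugs,
                              "rs": 0.0, "fdr": 1.0, "label": "none"})
        out = annotate_actionable(assoc, targets, cags)
        for _, row in out.iterrows():
            expected = any(
                t in cags for t in targets[targets["drug"] == row["drug"]]["target"]
            )
            assert row["targets_cag"] == expected
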