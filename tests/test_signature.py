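"""Translation-group classification, signature derivation and scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import valtrans as vt
from valtrans.signature import _ssgsea_one


def pairs_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "protein_log2fc", "rna_log2fc"])


class TestClassifyTranslationGroups:
    @pytest.mark.parametrize(
        "protein,rna,expected",
        [
            (-0.5, 0.2, "translation_down"),
            (-0.5, -1.5, "concordant"),  # mRNA-driven, not translation_down
            (0.4, 0.0, "translation_up"),
            (-0.1, 0.0, "unclassified"),
            (0.5, 1.5, "concordant"),
            (-0.32, 0.0, "unclassified"),  # strict inequality at the cut
        ],
    )
    def test_threshold_rules(self, protein, rna, expected):
        out = vt.classify_translation_groups(pairs_df([("g", protein, rna)]))
        assert out["group"].iloc[0] == expected

    def test_missing_values_dropped(self):
        out = vt.classify_translation_groups(pairs_df([("a", -0.5, 0.0), ("b", None, 0.0)]))
        assert list(out["gene_id"]) == ["a"]

    def test_matches_brute_force_set_logic(self):
        """Vectorized classifier equals explicit per-gene logic on a toy table."""
        toy = pairs_df([
            ("g1", -0.5, 0.2), ("g2", -0.4, -0.1), ("g3", 0.5, 0.3),
            ("g4", -0.2, 0.0), ("g5", -1.0, -1.4), ("g6", 0.9, 0.5),
        ])
        out = vt.classify_translation_groups(toy).set_index("gene_id")["group"]
        for row in toy.itertuples():
            if abs(row.rna_log2fc) < 1 and row.protein_log2fc < -0.32:
                assert out[row.gene_id] == "translation_down"
            elif abs(row.rna_log2fc) < 1 and row.protein_log2fc > 0.32:
                assert out[row.gene_id] == "translation_up"
            else:
                assert out[row.gene_id] != "translation_down"


class TestDeriveSignature:
    def test_toy_intersection(self):
        toy = pairs_df([
            ("g1", -0.5, 0.2), ("g2", -0.6, 0.1), ("g3", -0.9, 0.0),
            ("g4", 0.5, 0.1), ("g5", 0.1, 0.1), ("g6", -0.1, 0.1),
        ])
        classified = vt.classify_translation_groups(toy)
        sig = vt.derive_signature(classified, {"g1", "g2", "g5"})
        assert sig.genes == {"g1", "g2"}

    def test_universe_members_identity(self):
        toy = pairs_df([("g1", -0.5, 0.2), ("g2", 0.5, 0.2)])
        classified = vt.classify_translation_groups(toy)
        sig = vt.derive_signature(classified, {"g1", "g2"})
        assert sig.genes == {"g1"}

    def test_empty_intersection_is_valid(self):
        toy = pairs_df([("g1", -0.5, 0.2)])
        classified = vt.classify_translation_groups(toy)
        assert len(vt.derive_signature(classified, {"other"})) == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from([f"g{i}" for i in range(12)])),
           st.sets(st.sampled_from([f"g{i}" for i in range(12)])))
    def test_monotone_in_members(self, members, extra):
        """Enlarging the content-member set never shrinks the signature."""
        rng = np.random.default_rng(0)
        toy = pairs_df([(f"g{i}", float(rng.normal(-0.4, 0.4)), float(rng.normal(0, 0.5)))
                        for i in range(12)])
        classified = vt.classify_translation_groups(toy)
        small = vt.derive_signature(classified, members)
        large = vt.derive_signature(classified, members | extra)
        assert small.genes <= large.genes


class TestSuperpositionTest:
    def test_worked_contingency(self):
        calls = []
        # (a,b,c,d) = (12,8,238,742): build a table realizing these margins
        gid = 0
        for n, in_sig, down in [(12, True, True), (8, True, False),
                                (238, False, True), (742, False, False)]:
            for _ in range(n):
                calls.append({"gene_id": f"g{gid}", "log2fc": -1.0 if down else 1.0,
                              "significant": down})
                gid += 1
        sig_genes = {f"g{i}" for i in range(20)}
        res = vt.superposition_test(sig_genes, pd.DataFrame(calls), direction="down")
        assert res["chi2"] == pytest.approx(13.33, abs=0.005)
        assert res["table"] == ((12, 8), (238, 742))

    def test_identical_sets_maximal_association(self):
        calls = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(100)],
            "log2fc": [-1.0] * 30 + [1.0] * 70,
            "significant": [True] * 30 + [False] * 70,
        })
        res = vt.superposition_test({f"g{i}" for i in range(30)}, calls)
        assert res["p"] < 1e-15

    def test_independent_random_set_null(self):
        rng = np.random.default_rng(1)
        pvals = []
        for _ in range(100):
            down = rng.random(200) < 0.3
            calls = pd.DataFrame({
                "gene_id": [f"g{i}" for i in range(200)],
                "log2fc": np.where(down, -1.0, 1.0),
                "significant": down,
            })
            sig = {f"g{i}" for i in rng.choice(200, 40, replace=False)}
            pvals.append(vt.superposition_test(sig, calls)["p"])
        assert np.mean(np.array(pvals) < 0.05) < 0.15


class TestFilterLowCounts:
    GROUPS = {"a1": "g1", "a2": "g1", "a3": "g1", "b1": "g2", "b2": "g2", "b3": "g2"}

    def test_kept_when_one_group_well_detected(self):
        m = pd.DataFrame({"a1": [12], "a2": [12], "a3": [12],
                          "b1": [0], "b2": [0], "b3": [12]}, index=["geneA"])
        assert "geneA" in vt.filter_low_counts(m, self.GROUPS).index

    def test_removed_when_both_groups_sparse(self):
        m = pd.DataFrame({"a1": [0], "a2": [0], "a3": [15],
                          "b1": [3], "b2": [2], "b3": [20]}, index=["geneB"])
        assert len(vt.filter_low_counts(m, self.GROUPS)) == 0

    def test_identity_when_all_counts_high(self):
        m = pd.DataFrame(np.full((5, 6), 50), columns=list(self.GROUPS),
                         index=[f"g{i}" for i in range(5)])
        assert vt.filter_low_counts(m, self.GROUPS).equals(m)


class TestLogCpm:
    def test_zero_count_million_library(self):
        m = pd.DataFrame({"s": [0] + [1] * 10}, index=[f"g{i}" for i in range(11)])
        m["s"] = m["s"] * 0 + 0  # gene 0 stays 0
        m.iloc[1:, 0] = 99999  # library size ~1e6
        m.iloc[1, 0] = 1000000 - 99999 * 9
        assert m["s"].sum() == pytest.approx(1e6)
        assert vt.log_cpm(m).iloc[0, 0] == pytest.approx(-1.0, abs=0.01)

    def test_scale_invariance_up_to_pseudocount(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(100, 1000, (20, 3)).astype(float),
                         columns=list("abc"))
        doubled = m * 2
        assert np.allclose(vt.log_cpm(m), vt.log_cpm(doubled), atol=0.01)

    def test_recovers_cpm_magnitude(self):
        m = pd.DataFrame({"s": [2000.0] + [1.0] * 999})
        # count/libsize*1e6 ~ 2000/3000*1e6; log2 of that
        expected = np.log2((2000 + 0.5) / (m["s"].sum() + 1) * 1e6)
        assert vt.log_cpm(m).iloc[0, 0] == pytest.approx(expected)


class TestSsgseaScore:
    def make_expr(self, seed=3, n_genes=50, n_samples=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.random((n_genes, n_samples)) * 100,
                            index=[f"g{i}" for i in range(n_genes)],
                            columns=[f"s{j}" for j in range(n_samples)])

    def test_top_ranked_signature_is_maximal(self):
        expr = self.make_expr()
        sig = set(expr["s0"].nlargest(8).index)
        in_sig = expr.index.isin(sig)
        base = _ssgsea_one(expr["s0"], in_sig, 0.25)
        rng = np.random.default_rng(4)
        for _ in range(20):
            permuted = pd.Series(rng.permutation(expr["s0"].to_numpy()), index=expr.index)
            assert _ssgsea_one(permuted, in_sig, 0.25) <= base + 1e-12

    def test_invariant_under_monotone_transform(self):
        expr = self.make_expr()
        sig = {f"g{i}" for i in range(0, 50, 7)}
        a = vt.ssgsea_score(expr, sig, normalize=False)
        b = vt.ssgsea_score(np.exp(expr / 30.0), sig, normalize=False)
        assert np.allclose(a, b, atol=1e-9)

    def test_constant_vector_scores_zero(self):
        expr = self.make_expr()
        expr["s0"] = 5.0
        scores = vt.ssgsea_score(expr, {f"g{i}" for i in range(5)}, normalize=False)
        assert scores["s0"] == 0.0

    def test_signature_equal_universe_degenerate(self):
        expr = self.make_expr()
        scores = vt.ssgsea_score(expr, set(expr.index), normalize=False)
        assert (scores == 0).all()

    def test_planted_high_samples_rank_top(self):
        for seed in range(5):
            sig = [f"G{i:05d}" for i in range(40)]
            expr, high = vt.generate_expression_matrix(
                200, 30, sig, 5, 1.0, seed=seed)
            scores = vt.ssgsea_score(vt.log_cpm(expr), set(sig))
            assert sorted(scores.nlargest(5).index) == high

    def test_rank_agreement_with_gseapy(self):
        """Independent cross-check: sample ordering agrees with gseapy's ssGSEA."""
        gp = pytest.importorskip("gseapy")
        from scipy.stats import spearmanr
        expr = self.make_expr(seed=6, n_genes=80, n_samples=8)
        sig = sorted({f"g{i}" for i in range(0, 80, 5)})
        mine = vt.ssgsea_score(expr, set(sig), normalize=False)
        res = gp.ssgsea(data=expr, gene_sets={"s": sig}, outdir=None,
                        sample_norm_method="rank", min_size=2, seed=7)
        theirs = res.res2d.set_index("Name")["ES"].astype(float).reindex(mine.index)
        rho, _ = spearmanr(mine.to_numpy(), theirs.to_numpy())
        assert rho > 0.9


class TestGroupExtremes:
    def test_fifteen_percent_of_233_is_35(self):
        scores = pd.Series(np.linspace(-1, 1, 233),
                           index=[f"p{i:03d}" for i in range(233)])
        labels = vt.group_extremes(scores, frac=0.15)
        counts = labels.value_counts()
        assert counts["high"] == 35 and counts["low"] == 35

    def test_small_n(self):
        scores = pd.Series(range(20), index=[f"s{i:02d}" for i in range(20)])
        counts = vt.group_extremes(scores, frac=0.15).value_counts()
        assert counts["high"] == counts["low"] == 3

    def test_partition_and_order(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=40), index=[f"s{i:02d}" for i in range(40)])
        labels = vt.group_extremes(scores)
        assert set(labels.unique()) == {"high", "low", "middle"}
        assert scores[labels == "high"].min() >= scores[labels == "middle"].max()
        assert scores[labels == "middle"].min() >= scores[labels == "low"].max()

    def test_empty_middle_allowed_but_overlap_rejected(self):
        scores = pd.Series(range(10), index=[f"s{i}" for i in range(10)])
        labels = vt.group_extremes(scores, frac=0.5)
        assert (labels != "middle").all()
        with pytest.raises(ValueError):
            vt.group_extremes(scores, frac=0.6)


class TestRelativeFragmentation:
    def test_null_case(self):
        assert vt.relative_fragmentation(20.0, 20.0) == 1.0

    def test_worked_example(self):
        assert vt.relative_fragmentation(45.0, 20.0) == pytest.approx(32.25)

    def test_resensitization_sign(self):
        assert vt.relative_fragmentation(20.0, 45.0) < 1.0

    def test_saturated_spontaneous_rejected(self):
        with pytest.raises(ValueError):
            vt.relative_fragmentation(50.0, 100.0)
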