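import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from refmireo.io_core import ExpressionMatrix, SampleAnnotation, SignatureSet
from refmireo.signatures_scoring import (
    hypergeometric_overlap,
    ssgsea_scores,
    subtype_specific_mirnas,
    two_group_de,
)

from oracles import hypergeom_upper_tail_exact


class TestHypergeometricOverlap:
    def test_lineage_marker_overlap_between_reference_panels(self):
        # 148- and 136-member differential sets sharing 80 of 777 features
        res = hypergeometric_overlap(777, 148, 136, 80)
        assert res.p_value == pytest.approx(7.88371e-32, rel=5e-3)

    def test_blood_vs_lineage_overlap(self):
        res = hypergeometric_overlap(777, 112, 78, 27)
        assert res.p_value == pytest.approx(1.54e-6, rel=5e-3)

    def test_zero_overlap_is_certain(self):
        assert hypergeometric_overlap(100, 10, 20, 0).p_value == 1.0

    def test_symmetric_in_set_sizes(self):
        a = hypergeometric_overlap(500, 60, 40, 12).p_value
        b = hypergeometric_overlap(500, 40, 60, 12).p_value
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("N,K,n,k", [(20, 8, 6, 3), (50, 10, 10, 5), (30, 15, 4, 4)])
    def test_matches_exact_rational_oracle(self, N, K, n, k):
        assert hypergeometric_overlap(N, K, n, k).p_value == pytest.approx(
            hypergeom_upper_tail_exact(N, K, n, k), rel=1e-12
        )

    def test_overlap_exceeding_sets_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(100, 5, 8, 6)


def cohort(values, feats, n_a, n_b, label_a="disease", label_b="healthy"):
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    expr = ExpressionMatrix(feats, samples, values, scale="log2")
    ann = SampleAnnotation(samples, [label_a] * n_a + [label_b] * n_b)
    return expr, ann


class TestTwoGroupDE:
    def test_duplicated_groups_flag_nothing(self):
        rng = np.random.default_rng(3)
        block = rng.normal(5, 1, size=(20, 6))
        expr, ann = cohort(np.hstack([block, block]), [f"f{i}" for i in range(20)], 6, 6)
        assert sum(s.flagged for s in two_group_de(expr, ann)) == 0

    def test_spiked_features_recovered_with_direction(self):
        rng = np.random.default_rng(4)
        n = 20
        base = rng.normal(6, 1, size=(50, 1))
        vals = base + rng.normal(0, 0.25, size=(50, 2 * n))
        vals[:10, :n] += 1.0  # group A up by log2FC 1.0
        expr, ann = cohort(vals, [f"f{i:02d}" for i in range(50)], n, n)
        stats = two_group_de(expr, ann)
        flagged = {s.feature for s in stats if s.flagged}
        assert {f"f{i:02d}" for i in range(10)} <= flagged
        for s in stats:
            if s.feature in {f"f{i:02d}" for i in range(10)}:
                assert s.log2fc > 0

    def test_fold_change_gate_excludes_small_effects(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(5, 0.01, size=(30, 40))
        vals[0, :20] += 0.25  # strongly significant but below the 0.26 gate
        expr, ann = cohort(vals, [f"f{i}" for i in range(30)], 20, 20)
        s0 = two_group_de(expr, ann)[0]
        assert s0.fdr < 0.001 and abs(s0.log2fc) < 0.26
        assert not s0.flagged

    def test_constant_feature_p_one(self):
        vals = np.vstack([np.ones(8), np.arange(8.0)])
        expr, ann = cohort(vals, ["const", "varies"], 4, 4)
        assert two_group_de(expr, ann)[0].p_value == 1.0


class TestSubtypeSignatures:
    def test_boosted_feature_assigned_to_its_subtype(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(5, 0.1, size=(10, 9))
        vals[0, :3] += np.log2(10)  # 10x in subtype A only
        samples = [f"s{i}" for i in range(9)]
        expr = ExpressionMatrix([f"f{i}" for i in range(10)], samples, vals, scale="log2")
        ann = SampleAnnotation(samples, ["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        sigs = subtype_specific_mirnas(expr, ann)
        assert "f0" in sigs["A"]
        assert all("f0" not in sigs[g] for g in sigs.names() if g != "A")

    def test_fold_change_1p2_passes_gate(self):
        # log2(1.2) = 0.263 >= 0.26
        rng = np.random.default_rng(7)
        vals = rng.normal(5, 0.001, size=(5, 12))
        vals[0, :6] += np.log2(1.2)
        samples = [f"s{i}" for i in range(12)]
        expr = ExpressionMatrix([f"f{i}" for i in range(5)], samples, vals, scale="log2")
        ann = SampleAnnotation(samples, ["A"] * 6 + ["B"] * 6)
        assert "f0" in subtype_specific_mirnas(expr, ann)["A"]

    def test_matches_per_feature_recomputation(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(5, 1, size=(12, 10))
        samples = [f"s{i}" for i in range(10)]
        expr = ExpressionMatrix([f"f{i}" for i in range(12)], samples, vals, scale="log2")
        groups = ["A"] * 5 + ["B"] * 5
        ann = SampleAnnotation(samples, groups)
        sigs = subtype_specific_mirnas(expr, ann, lfc_min=0.1, fdr_max=0.4)
        # brute-force: loop each feature, Welch t for A vs rest, BH across features
        for target, idx_own, idx_rest in (("A", range(5), range(5, 10)), ("B", range(5, 10), range(5))):
            lfcs, ps = [], []
            for i in range(12):
                a, b = vals[i, list(idx_own)], vals[i, list(idx_rest)]
                lfcs.append(a.mean() - b.mean())
                ps.append(sps.ttest_ind(a, b, equal_var=False).pvalue)
            fdr = multipletests(ps, method="fdr_bh")[1]
            expected = {
                f"f{i}" for i in range(12) if lfcs[i] >= 0.1 and fdr[i] <= 0.4
            }
            got = set(sigs.signatures.get(target, []))
            assert got == expected

    def test_small_subtype_errors_with_name(self):
        vals = np.ones((3, 3))
        expr = ExpressionMatrix(["a", "b", "c"], ["s1", "s2", "s3"], vals)
        ann = SampleAnnotation(["s1", "s2", "s3"], ["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            subtype_specific_mirnas(expr, ann)


class TestSsgsea:
    def test_top_feature_signature_beats_bottom(self):
        vals = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        expr = ExpressionMatrix([f"f{i}" for i in range(5)], ["s"], vals)
        sigs = SignatureSet({"top": ["f0"], "bottom": ["f4"]})
        scores = ssgsea_scores(expr, sigs).to_frame()
        assert scores.loc["s", "top"] > scores.loc["s", "bottom"]

    def test_hand_computed_step_sum(self):
        # 5 features, one sample, set {f1, f3} (ranks 5 and 3 descending walk)
        vals = np.array([[5.0], [4.0], [3.0], [2.0], [1.0]])
        expr = ExpressionMatrix(["f1", "f2", "f3", "f4", "f5"], ["s"], vals)
        score = ssgsea_scores(expr, SignatureSet({"set": ["f1", "f3"]}), alpha=0.25).scores[0, 0]
        # walk: f1 (in, w=5^.25), f2 (out), f3 (in, w=3^.25), f4 (out), f5 (out)
        w1, w3 = 5.0**0.25, 3.0**0.25
        wt = w1 + w3
        expected = (
            (w1 / wt - 0.0)
            + (w1 / wt - 1.0 / 3.0)
            + (1.0 - 1.0 / 3.0)
            + (1.0 - 2.0 / 3.0)
            + (1.0 - 1.0)
        )
        assert score == pytest.approx(expected, rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(5, 2, size=(30, 4))
        feats = [f"f{i}" for i in range(30)]
        expr = ExpressionMatrix(feats, list("abcd"), vals)
        sigs = SignatureSet({"s1": feats[:5], "s2": feats[10:18]})
        a = ssgsea_scores(expr, sigs).scores
        transformed = ExpressionMatrix(feats, list("abcd"), np.exp2(vals) + 7.0, scale="linear")
        b = ssgsea_scores(transformed, sigs).scores
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_empty_effective_signature_errors(self):
        vals = np.ones((2, 1)) * np.array([[2.0], [1.0]])
        expr = ExpressionMatrix(["a", "b"], ["s"], vals)
        with pytest.raises(ValueError, match="ghost"):
            ssgsea_scores(expr, SignatureSet({"ghost": ["zz"]}))

    def test_score_tracks_subtype_proportion(self):
        # noise-free two-subtype mixture: raising a subtype's proportion raises
        # the mean score of its marker signature
        rng = np.random.default_rng(10)
        base = rng.normal(6, 1, size=(40, 2))
        base[:5, 0] += 4.0  # markers of subtype 0
        base[5:10, 1] += 4.0  # markers of subtype 1
        linear = np.exp2(base)
        props = np.array([[0.8, 0.2], [0.2, 0.8]])  # two blood samples
        blood = np.log2(linear @ props.T)
        feats = [f"f{i}" for i in range(40)]
        expr = ExpressionMatrix(feats, ["rich0", "rich1"], blood, scale="log2")
        sigs = SignatureSet({"sub0": feats[:5], "sub1": feats[5:10]})
        sc = ssgsea_scores(expr, sigs).to_frame()
        assert sc.loc["rich0", "sub0"] > sc.loc["rich1", "sub0"]
        assert sc.loc["rich1", "sub1"] > sc.loc["rich0", "sub1"]
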