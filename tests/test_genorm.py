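import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refstab import (
    ValidationError,
    genorm,
    m_values,
    normalization_factor,
    pairwise_v,
    pairwise_variation_matrix,
    stepwise_ranking,
)

from .oracles import genorm_m_oracle, genorm_stepwise_oracle


class TestPairwiseVariation:
    def test_identical_genes_have_zero_variation(self):
        q = pd.DataFrame([[1, 2, 4], [1, 2, 4]], index=["A", "B"], dtype=float)
        v = pairwise_variation_matrix(q)
        assert v.loc["A", "B"] == 0.0

    def test_hand_computed_value(self, worked_example):
        # log2 ratios of A against C are {0, 1, 2}: sample SD 1
        v = pairwise_variation_matrix(worked_example)
        assert v.loc["A", "C"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(v, v.T)
        assert np.all(np.diag(v) == 0)

    def test_scaling_a_gene_leaves_its_row_unchanged(self, worked_example):
        v1 = pairwise_variation_matrix(worked_example)
        scaled = worked_example.copy()
        scaled.loc["A"] *= 7.3
        v2 = pairwise_variation_matrix(scaled)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_rejects_single_gene(self, worked_example):
        with pytest.raises(ValidationError):
            pairwise_variation_matrix(worked_example.iloc[:1])


class TestMValues:
    def test_worked_example(self, worked_example):
        m = m_values(worked_example)
        assert m["A"] == pytest.approx(0.5, abs=1e-12)
        assert m["B"] == pytest.approx(0.5, abs=1e-12)
        assert m["C"] == pytest.approx(1.0, abs=1e-12)

    def test_two_identical_genes_both_zero(self):
        q = pd.DataFrame([[1, 2], [1, 2]], index=["A", "B"], dtype=float)
        assert m_values(q).max() == 0.0

    def test_gene_order_permutation_invariance(self, worked_example):
        m1 = m_values(worked_example)
        m2 = m_values(worked_example.iloc[::-1])
        for g in worked_example.index:
            assert m1[g] == pytest.approx(m2[g], abs=1e-14)

    def test_matches_brute_force_oracle(self, random_ct_tables):
        for t in random_ct_tables(5, seed=11):
            frame = 2.0 ** -pd.DataFrame(t.ct, index=list(t.gene_ids))
            m = m_values(frame)
            oracle = genorm_m_oracle(frame)
            for g in frame.index:
                assert m[g] == pytest.approx(oracle[g], abs=1e-10)

    def test_per_sample_scaling_invariance(self, random_ct_tables):
        # multiplying every gene in one sample by a constant models cDNA
        # loading differences; ratio-based M must not move
        t = random_ct_tables(1, seed=3)[0]
        frame = 2.0 ** -pd.DataFrame(t.ct, index=list(t.gene_ids))
        scaled = frame.copy()
        scaled.iloc[:, 2] *= 50.0
        np.testing.assert_allclose(
            m_values(frame), m_values(scaled), atol=1e-12
        )


class TestStepwiseRanking:
    def test_noisy_gene_removed_first(self, worked_example):
        r = stepwise_ranking(worked_example)
        assert r.removal_order == ("C",)
        assert set(r.order[:2]) == {"A", "B"}
        assert r.ranks["A"] == r.ranks["B"] == 1.5
        assert r.ranks["C"] == 3.0

    def test_all_identical_genes_lexicographic_tiebreak(self):
        q = pd.DataFrame(
            np.tile([1.0, 2.0, 4.0], (4, 1)), index=["d", "b", "a", "c"]
        )
        r = stepwise_ranking(q)
        # complete tie: the lexicographically smallest id is removed each round
        assert r.removal_order == ("a", "b")
        assert r.order[:2] == ("c", "d")
        assert m_values(q).max() == 0.0

    def test_matches_stepwise_oracle_on_random_tables(self, random_ct_tables):
        for t in random_ct_tables(20, seed=21):
            frame = 2.0 ** -pd.DataFrame(t.ct, index=list(t.gene_ids))
            r = stepwise_ranking(frame)
            removed, top = genorm_stepwise_oracle(frame)
            assert r.removal_order == removed
            assert tuple(sorted(r.order[:2])) == top

    def test_removing_worst_gene_never_raises_surviving_m(self, random_ct_tables):
        t = random_ct_tables(1, n_genes=6, seed=8)[0]
        frame = 2.0 ** -pd.DataFrame(t.ct, index=list(t.gene_ids))
        r = stepwise_ranking(frame)
        worst = r.removal_order[0]
        before = m_values(frame)
        after = m_values(frame.drop(index=worst))
        for g in after.index:
            assert after[g] <= before[g] + 1e-12

    def test_needs_three_genes(self, worked_example):
        with pytest.raises(ValidationError):
            stepwise_ranking(worked_example.iloc[:2])


class TestNormalizationFactor:
    def test_two_identical_genes(self, worked_example):
        nf = normalization_factor(worked_example, ["A", "B"], 2)
        np.testing.assert_allclose(nf, [1.0, 2.0, 4.0], atol=1e-12)

    def test_three_gene_geometric_mean(self, worked_example):
        nf = normalization_factor(worked_example, ["A", "B", "C"], 3)
        np.testing.assert_allclose(
            nf, [1.0, 4.0 ** (1 / 3), 16.0 ** (1 / 3)], atol=1e-12
        )

    def test_adding_constant_gene_compresses_geometrically(self, worked_example):
        # appending a constant-1 gene: NF_3 = NF_2 ** (2/3), so sample
        # *log*-ratios shrink by the factor 2/3 but the ordering is preserved
        nf2 = normalization_factor(worked_example, ["A", "B"], 2).to_numpy()
        nf3 = normalization_factor(worked_example, ["A", "B", "C"], 3).to_numpy()
        np.testing.assert_allclose(nf3, nf2 ** (2 / 3), atol=1e-12)
        assert np.all(nf3 <= nf2 + 1e-12)

    @pytest.mark.parametrize("n", [1, 4])
    def test_n_out_of_range(self, worked_example, n):
        with pytest.raises(ValidationError):
            normalization_factor(worked_example, ["A", "B", "C"], n)


class TestPairwiseV:
    def test_worked_example_v23(self, worked_example):
        curve, _ = pairwise_v(worked_example, ["A", "B", "C"])
        assert curve[0][0] == 2
        assert curve[0][1] == pytest.approx(1 / 3, abs=1e-12)

    def test_copy_of_geometric_mean_gives_zero_v(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.05, 1.0, (3, 6))
        extra = np.exp(np.log(base).mean(axis=0, keepdims=True))
        q = pd.DataFrame(np.vstack([base, extra]), index=["A", "B", "C", "D"])
        curve, _ = pairwise_v(q, ["A", "B", "C", "D"])
        v3 = dict((n, v) for n, v in curve)[3]
        assert v3 == pytest.approx(0.0, abs=1e-12)

    def test_no_crossing_returns_none(self, worked_example):
        _, rec = pairwise_v(worked_example, ["A", "B", "C"], cutoff=0.15)
        assert rec is None  # V_2/3 = 1/3: screening should continue

    def test_per_sample_scaling_invariance(self, random_ct_tables):
        t = random_ct_tables(1, n_genes=6, seed=13)[0]
        frame = 2.0 ** -pd.DataFrame(t.ct, index=list(t.gene_ids))
        order = stepwise_ranking(frame).order
        c1, _ = pairwise_v(frame, order)
        scaled = frame.copy()
        scaled.iloc[:, 0] *= 9.0
        c2, _ = pairwise_v(scaled, order)
        np.testing.assert_allclose(
            [v for _, v in c1], [v for _, v in c2], atol=1e-12
        )


class TestFullRun:
    def test_genorm_bundles_all_components(self, worked_example):
        res = genorm(worked_example)
        assert res.recommended_n is None
        assert res.cutoff == 0.15
        assert res.v_curve[0][1] == pytest.approx(1 / 3, abs=1e-12)
        assert res.m["C"] == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_noisy_gene_always_removed_first(self, seed):
        # one gene with big independent noise among two perfectly coupled ones
        rng = np.random.default_rng(seed)
        coupled = rng.uniform(0.1, 1.0, 6)
        noisy = coupled * 2.0 ** rng.normal(0, 2.0, 6)
        q = pd.DataFrame(
            [coupled, coupled, noisy / noisy.max()], index=["A", "B", "N"]
        )
        assert stepwise_ranking(q).removal_order[0] == "N"
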