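import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from refstab import (
    CtSimSpec,
    ValidationError,
    ct_to_quantity,
    decompose_variance,
    normfinder,
    preset_ct_spec,
    simulate_ct,
    stability_values,
)


def quantities(spec):
    table, truth = simulate_ct(spec)
    return ct_to_quantity(table, assume_perfect=True), truth


def two_group_spec(delta, sigma, seed=0, n=3, loading_sd=0.2):
    k = len(delta)
    return CtSimSpec(
        gene_ids=tuple(f"g{i+1}" for i in range(k)),
        group_sizes={"a": n, "b": n},
        mu=tuple(24.0 + i for i in range(k)),
        sigma=tuple(sigma),
        delta=tuple(tuple(row) for row in delta),
        loading_sd=loading_sd,
        seed=seed,
    )


class TestDecomposition:
    def test_noise_free_no_effects_gives_zeros(self):
        q, _ = quantities(
            two_group_spec([(0, 0)] * 4, [0] * 4, loading_sd=0.0)
        )
        d, s2, trunc = decompose_variance(q)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
        np.testing.assert_allclose(s2, 0.0, atol=1e-12)
        assert not trunc.to_numpy().any()

    def test_single_perturbed_gene_dominates_d_and_sums_to_zero(self):
        # +1 cycle for g1 in group b only, no noise: g1 has the largest |d|
        d, s2, _ = decompose_variance(
            quantities(
                two_group_spec(
                    [(0, 1.0), (0, 0), (0, 0), (0, 0)], [0] * 4, loading_sd=0.0
                )
            )[0]
        )
        assert d.abs().idxmax().eq("g1").all()
        np.testing.assert_allclose(d.sum(axis=0), 0.0, atol=1e-9)

    def test_d_columns_sum_to_zero_with_unbalanced_groups(self):
        spec = CtSimSpec(
            gene_ids=("g1", "g2", "g3"),
            group_sizes={"a": 2, "b": 5},
            mu=(20.0, 22.0, 24.0),
            sigma=(0.2, 0.3, 0.4),
            delta=((0.0, 0.5), (0.0, -0.2), (0.0, 0.0)),
            seed=9,
        )
        d, _, _ = decompose_variance(quantities(spec)[0])
        np.testing.assert_allclose(d.sum(axis=0), 0.0, atol=1e-9)

    def test_requires_three_genes_and_two_per_group(self):
        with pytest.raises(ValidationError, match="3 genes"):
            decompose_variance(quantities(two_group_spec([(0, 0)] * 2, [0.1] * 2))[0])
        bad = CtSimSpec(
            gene_ids=("a", "b", "c"),
            group_sizes={"x": 1, "y": 3},
            mu=(20.0,) * 3,
            sigma=(0.1,) * 3,
            seed=0,
        )
        with pytest.raises(ValidationError, match="need >= 2"):
            decompose_variance(quantities(bad)[0])

    def test_sigma2_method_of_moments_consistency(self):
        # n=200/group: per-gene mean estimate over replicates within 15%
        base = preset_ct_spec("treatment", seed=0, scenario="graded")
        true_sigma2 = np.asarray(base.sigma) ** 2
        estimates = []
        for seed in range(15):
            spec = CtSimSpec(
                gene_ids=base.gene_ids,
                group_sizes={"a": 200, "b": 200},
                mu=base.mu,
                sigma=base.sigma,
                loading_sd=0.2,
                seed=seed,
            )
            _, s2, _ = decompose_variance(quantities(spec)[0])
            estimates.append(s2.mean(axis=1).to_numpy())
        mean_est = np.mean(estimates, axis=0)
        np.testing.assert_allclose(mean_est, true_sigma2, rtol=0.15)


class TestStabilityValues:
    def test_perfectly_stable_gene_ranks_first(self):
        d = pd.DataFrame({"a": [0.0, 0.4], "b": [0.0, -0.4]}, index=["g1", "g2"])
        s2 = pd.DataFrame({"a": [0.0, 0.1], "b": [0.0, 0.1]}, index=["g1", "g2"])
        sv, ranks = stability_values(d, s2, {"a": 3, "b": 3})
        assert sv["g1"] == 0.0
        assert ranks["g1"] == 1.0

    def test_two_group_arithmetic(self):
        d = pd.DataFrame({"a": [0.5], "b": [-0.5]}, index=["g"])
        s2 = pd.DataFrame({"a": [0.0], "b": [0.0]}, index=["g"])
        sv, _ = stability_values(d, s2, {"a": 3, "b": 3})
        assert sv["g"] == pytest.approx(0.5)

    def test_single_group_reduces_to_sqrt_sigma2(self):
        s2 = pd.DataFrame({"all": [0.04, 0.09]}, index=["g1", "g2"])
        d = s2 * 0.0
        sv, _ = stability_values(d, s2, {"all": 6})
        assert sv["g1"] == pytest.approx(0.2)
        assert sv["g2"] == pytest.approx(0.3)


class TestNormfinderEndToEnd:
    def test_ranking_recovers_graded_instability(self):
        # Spearman(true instability, SV) averaged over seeds must be high
        rhos = []
        for seed in range(50):
            q, truth = quantities(preset_ct_spec("stages", seed=seed))
            res = normfinder(q)
            t = truth.true_instability()
            rhos.append(
                spearmanr(t.to_numpy(), res.sv.reindex(t.index).to_numpy()).statistic
            )
        assert np.mean(rhos) >= 0.9

    def test_sv_invariant_to_per_sample_loading_shifts(self):
        spec = two_group_spec([(0, 0.3)] * 4, [0.2] * 4, seed=5, loading_sd=0.0)
        table, _ = simulate_ct(spec)
        q1 = ct_to_quantity(table, assume_perfect=True)
        shifted = table.ct.copy()
        shifted[:, 1] += 2.5  # shared loading shift on one sample
        t2 = type(table)(table.gene_ids, table.sample_ids, shifted, table.groups)
        q2 = ct_to_quantity(t2, assume_perfect=True)
        r1, r2 = normfinder(q1), normfinder(q2)
        np.testing.assert_allclose(r1.sv, r2.sv, atol=1e-9)

    def test_increasing_group_effect_increases_sv(self):
        svs = []
        for delta in (0.0, 0.4, 0.8, 1.2):
            q, _ = quantities(
                two_group_spec(
                    [(0, delta), (0, 0), (0, 0), (0, 0)],
                    [0.0] * 4,
                    loading_sd=0.0,
                )
            )
            svs.append(normfinder(q).sv["g1"])
        assert all(a < b for a, b in zip(svs, svs[1:]))

    def test_ungrouped_mode_matches_single_label_grouping(self):
        q, _ = quantities(preset_ct_spec("treatment", seed=2))
        pooled = normfinder(q, ungrouped=True)
        same = normfinder(q.to_frame(), groups={s: "one" for s in q.sample_ids})
        np.testing.assert_allclose(pooled.sv, same.sv, atol=1e-12)

    def test_negative_variance_truncation_recorded(self):
        # noise-free data with group effects: moment estimates dip below 0
        q, _ = quantities(
            two_group_spec([(0, 1.0), (0, 0), (0, 0)], [0, 0.3, 0.3], seed=1)
        )
        res = normfinder(q)
        assert res.truncated.to_numpy().any()
        assert (res.sigma2.to_numpy() >= 0).all()
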