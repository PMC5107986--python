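import numpy as np
import pandas as pd
import pytest

from refstab.genorm import (
    genorm_ranking,
    m_values,
    normalization_factor,
    pairwise_gene_variation,
    pairwise_v,
)
from refstab.qpcr_core import relative_quantities
from refstab.synthetic_data import SimulationConfig, simulate_ct_dataset

from conftest import q_from_log2, random_ct


def brute_force_m(q, genes):
    """Independent double-loop oracle for M."""
    log_q = np.log2(q.values.loc[genes].to_numpy(dtype=float))
    out = {}
    for i, g in enumerate(genes):
        sds = [
            np.std(log_q[i] - log_q[j], ddof=1)
            for j in range(len(genes))
            if j != i
        ]
        out[g] = float(np.mean(sds))
    return pd.Series(out)


class TestPairwiseVariation:
    def test_identical_rows_zero(self):
        q = q_from_log2({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert pairwise_gene_variation(q, "A", "B") == 0.0

    def test_hand_value_and_symmetry(self):
        q = q_from_log2({"A": [0, 1, 2], "B": [0, 0, 0]})
        assert pairwise_gene_variation(q, "A", "B") == pytest.approx(1.0)
        assert pairwise_gene_variation(q, "B", "A") == pytest.approx(1.0)

    def test_scaling_invariance(self):
        q1 = q_from_log2({"A": [0, 1, 2], "B": [0.3, 0.1, 0.9]})
        q2 = q_from_log2({"A": [5, 6, 7], "B": [0.3, 0.1, 0.9]})
        assert pairwise_gene_variation(q1, "A", "B") == pytest.approx(
            pairwise_gene_variation(q2, "A", "B")
        )


class TestMValues:
    def test_hand_instance(self, three_gene_quantities):
        m = m_values(three_gene_quantities)
        assert m["A"] == pytest.approx(0.5)
        assert m["B"] == pytest.approx(0.5)
        assert m["C"] == pytest.approx(1.0)

    def test_identical_genes_all_zero(self):
        q = q_from_log2({g: [0, 1, 2, 1] for g in "ABCD"})
        assert (m_values(q) == 0).all()

    def test_sample_permutation_invariance(self, three_gene_quantities):
        q = three_gene_quantities
        shuffled = q.values[["s3", "s1", "s2"]]
        q2 = q_from_log2({g: list(np.log2(shuffled.loc[g])) for g in q.values.index})
        pd.testing.assert_series_equal(m_values(q), m_values(q2))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ct = random_ct(rng, n_genes=int(rng.integers(3, 8)), n_samples=int(rng.integers(3, 10)))
            q = relative_quantities(ct)
            genes = list(q.values.index)
            got = m_values(q)
            expected = brute_force_m(q, genes)
            assert np.allclose(got.to_numpy(), expected.reindex(got.index).to_numpy())


class TestRanking:
    def test_hand_instance_exclusion_and_pair(self, three_gene_quantities):
        res = genorm_ranking(three_gene_quantities)
        assert res.exclusion_order[0] == "C"
        assert res.best_pair == ("A", "B")
        assert res.final_m["C"] == pytest.approx(1.0)
        assert res.final_m["A"] == res.final_m["B"] == pytest.approx(0.0)

    def test_identical_genes_deterministic_tiebreak(self):
        q = q_from_log2({g: [0, 1, 2] for g in "ABCD"})
        res = genorm_ranking(q)
        # lexicographically last excluded first, all M = 0
        assert res.exclusion_order[:2] == ["D", "C"]
        assert res.tie_breaks == ["D", "C"]
        assert (res.final_m == 0).all()

    def test_gene_relabeling_invariance(self, three_gene_quantities):
        q = three_gene_quantities
        renamed = q_from_log2(
            {"X": [0, 1, 2], "Y": [0, 1, 2], "Z": [0, 0, 0]}
        )
        res1, res2 = genorm_ranking(q), genorm_ranking(renamed)
        mapping = {"A": "X", "B": "Y", "C": "Z"}
        assert [mapping[g] for g in res1.exclusion_order] == res2.exclusion_order

    def test_high_noise_gene_excluded_first(self):
        hits = 0
        for seed in range(100):
            genes = [f"g{i}" for i in range(5)]
            sds = {g: 0.05 for g in genes}
            sds["g4"] = 1.0
            cfg = SimulationConfig(genes=genes, noise_sd=sds)
            ct, _, _ = simulate_ct_dataset(cfg, seed)
            q = relative_quantities(ct)
            hits += genorm_ranking(q).exclusion_order[0] == "g4"
        assert hits >= 99


class TestNormalizationFactor:
    def test_single_gene_is_its_q_row(self, three_gene_quantities):
        nf = normalization_factor(three_gene_quantities, ["A"])
        assert np.allclose(nf, three_gene_quantities.values.loc["A"])

    def test_geometric_mean_in_log_space(self):
        q = q_from_log2({"A": [0, 1, 2], "B": [0, 0, 0]})
        nf = normalization_factor(q, ["A", "B"])
        assert np.allclose(nf, np.power(2.0, [0, 0.5, 1.0]))

    def test_missing_q_gives_missing_nf(self):
        q = q_from_log2({"A": [0, 1], "B": [0, 0]})
        q.values.loc["A", "s2"] = np.nan
        nf = normalization_factor(q, ["A", "B"])
        assert np.isnan(nf["s2"]) and nf["s1"] == 1.0


class TestPairwiseV:
    def test_hand_instance_v23(self, three_gene_quantities):
        res = pairwise_v(three_gene_quantities, genorm_ranking(three_gene_quantities))
        assert res.v_series["V2/3"] == pytest.approx(1.0 / 3.0)
        assert res.optimal_n == 3
        assert not res.threshold_met

    def test_identical_genes_optimal_two(self):
        q = q_from_log2({g: [0, 1, 2] for g in "ABCD"})
        res = pairwise_v(q, genorm_ranking(q))
        assert (res.v_series == 0).all()
        assert res.optimal_n == 2
        assert res.threshold_met

    def test_duplicating_most_stable_gene_never_increases_v23(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ct = random_ct(rng, n_genes=4, n_samples=6)
            q = relative_quantities(ct)
            res = pairwise_v(q, genorm_ranking(q))
            best = res.ranking[0]
            dup = q.values.copy()
            dup.loc["dup"] = q.values.loc[best]
            q2 = q_from_log2({g: list(np.log2(dup.loc[g])) for g in dup.index})
            res2 = pairwise_v(q2, genorm_ranking(q2))
            assert res2.v_series["V2/3"] <= res.v_series["V2/3"] + 1e-12
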