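import numpy as np
import pandas as pd
import pytest

from refstab.descriptive_stability import bestkeeper_descriptives, delta_ct_stability
from refstab.genorm import m_values
from refstab.prescreen import abundance_stats
from refstab.qpcr_core import fit_standard_curve, relative_quantities
from refstab.synthetic_data import (
    SampleCell,
    SimulationConfig,
    default_design,
    simulate_ct_dataset,
    simulate_dilution_series,
    simulate_fragment_counts,
)


class TestDesign:
    def test_default_design_is_the_14_sample_layout(self):
        design = default_design()
        assert len(design) == 14
        meta_counts = pd.Series([c.organ for c in design]).value_counts()
        assert meta_counts.to_dict() == {"leaf": 6, "fruit": 6, "flower": 2}
        assert {c.treatment for c in design} == {"control", "drought"}
        assert [c.sample_id for c in design][:4] == ["C-L3", "C-L4", "C-L7", "C-F"]

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SimulationConfig(genes=["a"], noise_sd={"a": -0.1})
        with pytest.raises(ValueError):
            SimulationConfig(genes=["a", "a"], noise_sd={"a": 0.1})
        with pytest.raises(ValueError):
            SimulationConfig(
                genes=["a"], noise_sd={"a": 0.1}, efficiencies={"a": 2.5}
            )


class TestCtSimulation:
    def test_zero_noise_gives_constant_rows_and_zero_scores(self):
        cfg = SimulationConfig(
            genes=["a", "b", "c"],
            noise_sd={g: 0.0 for g in "abc"},
            loading_sd=0.0,
            tech_rep_sd=0.0,
        )
        ct, _, _ = simulate_ct_dataset(cfg, 0)
        assert (ct.values.nunique(axis=1) == 1).all()
        assert np.allclose(m_values(relative_quantities(ct)), 0.0)
        assert np.allclose(delta_ct_stability(ct).scores, 0.0)

    def test_same_seed_reproducible(self):
        cfg = SimulationConfig.study_like()
        ct1, _, t1 = simulate_ct_dataset(cfg, 5)
        ct2, _, t2 = simulate_ct_dataset(cfg, 5)
        pd.testing.assert_frame_equal(ct1.values, ct2.values)
        pd.testing.assert_series_equal(t1.loading_factors, t2.loading_factors)

    def test_replicate_mean_matches_values(self):
        cfg = SimulationConfig.study_like()
        ct, _, _ = simulate_ct_dataset(cfg, 1)
        assert ct.replicates.shape == (10, 14, 3)
        np.testing.assert_allclose(ct.replicates.mean(axis=2), ct.values.to_numpy())

    def test_truth_ordering_puts_stable_genes_first(self):
        cfg = SimulationConfig.study_like()
        _, _, truth = simulate_ct_dataset(cfg, 0)
        assert truth.stability_ordering[:2] == ["gene01", "gene02"]

    def test_loading_invariance_of_ratio_statistics_not_bestkeeper(self):
        # log-ratio statistics cancel loading exactly per draw; BestKeeper's
        # raw-Ct SD inflates with it
        genes = [f"g{i}" for i in range(5)]
        m_shift, dct_shift, bk_lo, bk_hi = [], [], [], []
        for seed in range(30):
            res = {}
            for tau in (0.0, 1.0):
                cfg = SimulationConfig(
                    genes=genes, noise_sd={g: 0.2 for g in genes},
                    loading_sd=tau, tech_rep_sd=0.0,
                )
                ct, _, _ = simulate_ct_dataset(cfg, seed)
                res[tau] = ct
            m_shift.append(
                (m_values(relative_quantities(res[1.0]))
                 - m_values(relative_quantities(res[0.0]))).mean()
            )
            dct_shift.append(
                (delta_ct_stability(res[1.0]).scores
                 - delta_ct_stability(res[0.0]).scores).mean()
            )
            bk_lo.append(bestkeeper_descriptives(res[0.0]).stats["sd"].mean())
            bk_hi.append(bestkeeper_descriptives(res[1.0]).stats["sd"].mean())
        # identical substreams: the noise draw is the same, loading cancels exactly
        assert np.allclose(m_shift, 0.0, atol=1e-10)
        assert np.allclose(dct_shift, 0.0, atol=1e-10)
        assert np.mean(bk_hi) > np.mean(bk_lo) + 0.3

    def test_sample_duplication_leaves_single_group_rho_unbiased(self):
        from refstab.normfinder import normfinder_single_group

        design = [SampleCell(f"s{i}", "leaf", "3", "control") for i in range(20)]
        shifts = []
        for seed in range(50):
            cfg = SimulationConfig(
                genes=["a", "b", "c", "d"],
                noise_sd={"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4},
                design=design,
            )
            ct, _, _ = simulate_ct_dataset(cfg, seed)
            rho = normfinder_single_group(relative_quantities(ct)).stability
            doubled = pd.concat(
                [ct.values, ct.values.add_suffix("_dup", axis=1)], axis=1
            )
            from refstab.data_io import CtMatrix

            ct2 = CtMatrix(doubled, efficiencies=ct.efficiencies)
            rho2 = normfinder_single_group(relative_quantities(ct2)).stability
            shifts.append((rho2 - rho).mean())
        assert abs(np.mean(shifts)) < 0.01


class TestFragmentCounts:
    def test_poisson_limit_cv(self):
        genes = [f"g{i}" for i in range(20)]
        ok = 0
        for seed in range(20):
            cfg = SimulationConfig(
                genes=genes, noise_sd={g: 0.0 for g in genes}, loading_sd=0.0,
                fragment_mean={g: 10000.0 for g in genes},
            )
            table, _ = simulate_fragment_counts(cfg, seed)
            cv = abundance_stats(table).table["cv"]
            ok += (cv < 0.05).all()
        assert ok >= 19

    def test_large_dispersion_fails_prescreen_cv(self):
        genes = [f"g{i}" for i in range(20)]
        cfg = SimulationConfig(
            genes=genes, noise_sd={g: 0.0 for g in genes}, loading_sd=0.0,
            fragment_mean={g: 2000.0 for g in genes},
            fragment_dispersion={g: 1.0 for g in genes},  # size parameter 1
        )
        table, _ = simulate_fragment_counts(cfg, 0)
        cv = abundance_stats(table).table["cv"]
        assert (cv > 0.3).mean() > 0.5

    def test_same_seed_identical_table(self):
        cfg = SimulationConfig.study_like()
        t1, _ = simulate_fragment_counts(cfg, 9)
        t2, _ = simulate_fragment_counts(cfg, 9)
        pd.testing.assert_frame_equal(t1.values, t2.values)


class TestDilutionSeries:
    def test_default_six_five_fold_levels(self):
        series = simulate_dilution_series(2.0)
        assert len(np.unique(series.log10_amount)) == 6
        assert np.allclose(np.diff(np.unique(series.log10_amount)), np.log10(5.0))

    def test_known_efficiency_by_construction(self):
        fit = fit_standard_curve(simulate_dilution_series(1.913, noise_sd=0.0))
        assert fit.efficiency_percent == pytest.approx(91.3, abs=1e-9)

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_series(2.5)
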