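"""Tests of the synthetic family-data generator."""

import numpy as np
import pandas as pd
import pytest

from famblup.pedigree import Pedigree, PedigreeError, PedigreeRecord
from famblup.simulate import (ConfigError, SimulationConfig, prepare_traits,
                              simulate_genotypes, simulate_pedigree,
                              simulate_phenotypes)

from _oracles import replay_pedigree_count
from conftest import simulate_all


class TestPedigreeSimulation:
    def test_single_family_fixed_sibship_counts(self):
        cfg = SimulationConfig(n_families=1, generations=1, mean_sibship=2,
                               sibship_model="fixed", seed=0)
        ped = simulate_pedigree(cfg)
        assert len(ped) == 4  # founder couple + 2 terminal offspring
        assert len(ped.founder_ids) == 2
        gens = [r.generation for r in ped.records]
        assert sorted(gens) == [0, 0, 1, 1]

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="n_families"):
            SimulationConfig(n_families=0)
        with pytest.raises(ConfigError, match="h2"):
            SimulationConfig(h2=0.9, household_variance_fraction=0.3)
        with pytest.raises(ConfigError, match="missing_phenotype_rate"):
            SimulationConfig(missing_phenotype_rate=1.5)

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_total_count_matches_replay_oracle(self, seed):
        cfg = SimulationConfig(n_families=10, generations=3, mean_sibship=3,
                               seed=seed)
        ped = simulate_pedigree(cfg)
        assert len(ped) == replay_pedigree_count(seed, 10, 3, 3)

    def test_structure_invariants(self):
        ped = simulate_pedigree(SimulationConfig(n_families=5, generations=3,
                                                 mean_sibship=2, seed=1))
        ped.validate()
        # non-terminal offspring are mated to immigrant founders
        parents = {(r.father_id, r.mother_id) for r in ped.records
                   if r.father_id is not None}
        for fa, mo in parents:
            recs = [ped.records[ped.index_of(i)] for i in (fa, mo)]
            assert {recs[0].sex, recs[1].sex} == {"male", "female"}
            assert ped.is_founder(fa) or ped.is_founder(mo)


class TestGenotypeSimulation:
    def test_founder_pair_shares_nothing(self, small_dataset):
        ped, panel, ibd, _ = small_dataset
        f0, f1 = ped.index_of(ped.founder_ids[0]), ped.index_of(ped.founder_ids[1])
        assert np.all(ibd.pair_share(f0, f1) == 0.0)

    def test_parent_offspring_share_half_everywhere(self, small_dataset):
        ped, panel, ibd, _ = small_dataset
        child = next(r for r in ped.records if r.father_id is not None)
        ci = ped.index_of(child.individual_id)
        fi = ped.index_of(child.father_id)
        assert np.all(ibd.pair_share(ci, fi) == 0.5)

    def test_self_share_is_one_for_noninbred(self, small_dataset):
        ped, _, ibd, _ = small_dataset
        for i in range(0, len(ped), 7):
            assert np.all(ibd.pair_share(i, i) == 1.0)

    def test_fullsib_mean_share_near_half(self):
        """Monte-Carlo: full sibs share half the genome on average."""
        ped = Pedigree([
            PedigreeRecord("fa", None, None, "male", 0),
            PedigreeRecord("mo", None, None, "female", 0),
            PedigreeRecord("s1", "fa", "mo", "male", 1),
            PedigreeRecord("s2", "fa", "mo", "female", 1),
        ])
        means = []
        for rep in range(200):
            cfg = SimulationConfig(n_snps=100, n_chromosomes=10,
                                   ld_block_length_cM=0.0, seed=500 + rep)
            _, ibd = simulate_genotypes(ped, cfg)
            means.append(ibd.pair_share(2, 3).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) < 3 * se

    def test_dosage_consistent_with_map(self, small_dataset):
        _, panel, _, _ = small_dataset
        assert panel.dosage.shape == (panel.n_individuals, panel.n_snps)
        assert set(np.unique(panel.dosage)) <= {0, 1, 2}
        for c in np.unique(panel.chromosome):
            assert np.all(np.diff(panel.cM[panel.chromosome == c]) > 0)

    def test_ld_decays_with_distance(self):
        """The copying scheme yields high adjacent r² that fades with cM."""
        cfg = SimulationConfig(n_families=120, generations=1, mean_sibship=2,
                               n_snps=200, n_chromosomes=1,
                               ld_block_length_cM=4.0, seed=9)
        ped = simulate_pedigree(cfg)
        panel, _ = simulate_genotypes(ped, cfg)
        d = panel.dosage.astype(float)
        d -= d.mean(axis=0)
        sd = d.std(axis=0)
        ok = sd > 0
        z = d[:, ok] / sd[ok]
        r_adj = np.mean([(z[:, j] * z[:, j + 1]).mean() ** 2
                         for j in range(0, z.shape[1] - 1, 2)])
        far = z.shape[1] // 2
        r_far = np.mean([(z[:, j] * z[:, j + far]).mean() ** 2
                         for j in range(0, far, 2)])
        assert r_adj > 5 * r_far

    def test_unknown_parent_raises(self):
        with pytest.raises(PedigreeError, match="ghost"):
            Pedigree([PedigreeRecord("kid", "ghost", "ghost2", "male", 1)])


class TestPhenotypeSimulation:
    def test_no_heritability_means_no_genetic_signal(self):
        cfg0 = SimulationConfig(n_families=40, generations=2, mean_sibship=3,
                                n_snps=60, n_chromosomes=3, h2=0.0,
                                household_variance_fraction=0.0,
                                missing_phenotype_rate=0.0, seed=77)
        ped = simulate_pedigree(cfg0)
        panel, ibd = simulate_genotypes(ped, cfg0)
        t0 = simulate_phenotypes(ped, panel, ibd, cfg0)
        assert np.allclose(t0["true_breeding_value"], 0.0)
        # the same stream with h2 > 0 exposes the latent genetic draw; the
        # h2 = 0 trait must be uncorrelated with it
        cfg4 = SimulationConfig(**{**cfg0.__dict__, "h2": 0.4})
        t4 = simulate_phenotypes(ped, panel, ibd, cfg4)
        r = np.corrcoef(prepare_traits(t0)["trait_pre"],
                        t4["true_breeding_value"])[0, 1]
        assert abs(r) < 0.1

    def test_trait_regresses_one_to_one_on_breeding_value(self):
        """Across replicates the trait has unit slope on the true BV."""
        cfg = SimulationConfig(n_families=120, generations=2, mean_sibship=3,
                               n_snps=30, n_chromosomes=3, h2=0.4,
                               missing_phenotype_rate=0.0, seed=100)
        ped = simulate_pedigree(cfg)
        panel, ibd = simulate_genotypes(ped, cfg)
        assert len(ped) >= 2000
        slopes = []
        for rep in range(100):
            t = simulate_phenotypes(ped, panel, ibd, cfg.with_seed(100 + rep))
            t = prepare_traits(t)
            bv = t["true_breeding_value"].to_numpy()
            y = t["trait_pre"].to_numpy()
            slopes.append(np.polyfit(bv, y, 1)[0])
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - 1.0) < 3 * se

    def test_variance_decomposition_recovers_h2(self):
        """var(BV) / var(trait net of covariates) ≈ h2 across replicates."""
        cfg = SimulationConfig(n_families=120, generations=2, mean_sibship=3,
                               n_snps=30, n_chromosomes=3, h2=0.4,
                               household_variance_fraction=0.2,
                               missing_phenotype_rate=0.0,
                               measurement_error_sd=0.0, seed=200)
        ped = simulate_pedigree(cfg)
        panel, ibd = simulate_genotypes(ped, cfg)
        ratios = []
        for rep in range(100):
            t = prepare_traits(simulate_phenotypes(ped, panel, ibd,
                                                   cfg.with_seed(300 + rep)))
            X = np.column_stack([
                np.ones(len(t)), t["age"],
                (t["sex"] == "male").astype(float),
                (t["center"] == "C2").astype(float), t["smoking"]])
            y = t["trait_pre"].to_numpy()
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            ratios.append(t["true_breeding_value"].var() / resid.var())
        assert abs(np.mean(ratios) - cfg.h2) < 0.03

    def test_missing_phenotype_count_exact(self):
        cfg = SimulationConfig(n_families=60, generations=2, mean_sibship=3,
                               n_snps=40, n_chromosomes=2,
                               missing_phenotype_rate=0.1, seed=5)
        ped, panel, ibd, pheno = simulate_all(cfg)
        n_missing = pheno["trait_pre"].isna().sum()
        assert n_missing == round(0.1 * len(ped))
        assert (pheno["trait_pre"].isna() == pheno["trait_post"].isna()).all()

    def test_treatment_shift_applied_to_post(self):
        cfg = SimulationConfig(n_families=60, generations=2, mean_sibship=3,
                               n_snps=40, n_chromosomes=2,
                               treatment_mean_shift=-0.3,
                               missing_phenotype_rate=0.0, seed=8)
        _, _, _, pheno = simulate_all(cfg)
        diff = (pheno["trait_post"] - pheno["trait_pre"]).mean()
        assert abs(diff - (-0.3)) < 0.05

    def test_household_members_share_effects(self):
        cfg = SimulationConfig(n_families=30, generations=2, mean_sibship=3,
                               n_snps=40, n_chromosomes=2, h2=0.0,
                               household_variance_fraction=0.6,
                               missing_phenotype_rate=0.0, seed=13)
        _, _, _, pheno = simulate_all(cfg)
        grp = pheno.groupby("household_id")["trait_pre"]
        within = grp.var().mean()
        total = pheno["trait_pre"].var()
        assert within < total  # household effect induces within-group clustering

    def test_full_determinism(self, small_config):
        a = simulate_all(small_config)
        b = simulate_all(small_config)
        assert a[0].ids == b[0].ids
        assert np.array_equal(a[1].dosage, b[1].dosage)
        assert np.array_equal(a[2].labels, b[2].labels)
        pd.testing.assert_frame_equal(a[3], b[3])
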