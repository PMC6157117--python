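"""Tests of the relationship-matrix constructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famblup.kinship import (KinshipDataError, RelationshipMatrix, SnpWeights,
                             grm_unweighted, grm_weighted, ibd_moment_kinship,
                             ld_weights, normalize_diagonal,
                             pedigree_relationship, repair_psd)
from famblup.pedigree import Pedigree, PedigreeRecord
from famblup.simulate import GenotypePanel, SimulationConfig, \
    simulate_genotypes, simulate_pedigree

from _oracles import path_counting_relationship


def make_panel(dosage, cM=None, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    cM = np.arange(m, dtype=float) + 1.0 if cM is None else np.asarray(cM, float)
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    return GenotypePanel([f"i{k}" for k in range(n)],
                         [f"s{j}" for j in range(m)], dosage, chrom, cM,
                         np.round(cM * 1e6).astype(np.int64),
                         dosage.mean(axis=0) / 2.0)


class TestPedigreeRelationship:
    def test_nuclear_family_values(self, nuclear_family):
        A = pedigree_relationship(nuclear_family).values
        ids = nuclear_family.ids
        fa, mo, c1, c2 = (ids.index(x) for x in ("fa", "mo", "c1", "c2"))
        assert A[fa, c1] == 0.5          # parent-offspring
        assert A[c1, c2] == 0.5          # full sibs
        assert A[fa, mo] == 0.0
        assert np.all(np.diag(A) == 1.0)

    def test_half_sibs_and_inbred_diagonal(self, halfsib_mating_pedigree):
        A = pedigree_relationship(halfsib_mating_pedigree).values
        ids = halfsib_mating_pedigree.ids
        h1, h2, inb = (ids.index(x) for x in ("h1", "h2", "inb"))
        assert A[h1, h2] == 0.25         # half sibs
        assert A[inb, inb] == 1.125      # 1 + half-sib-mating inbreeding

    @pytest.mark.parametrize("seed", [3, 9])
    def test_matches_path_counting_oracle(self, seed):
        cfg = SimulationConfig(n_families=2, generations=2, mean_sibship=2,
                               seed=seed)
        ped = simulate_pedigree(cfg)
        assert len(ped) <= 30
        A = pedigree_relationship(ped).values
        np.testing.assert_allclose(A, path_counting_relationship(ped),
                                   atol=1e-12)


class TestGrm:
    def test_single_snp_formula(self):
        panel = make_panel([[2], [0]])
        # needs >= 2 SNPs; duplicate the SNP and halve nothing: scale invariant
        panel = make_panel([[2, 2], [0, 0]])
        G = grm_unweighted(panel).values
        np.testing.assert_allclose(G, [[2, -2], [-2, 2]], atol=1e-12)

    def test_duplicate_individuals(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(1, 50))
        panel = make_panel(np.vstack([d, d, rng.integers(0, 3, size=(3, 50))]))
        G = grm_unweighted(panel).values
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-10)
        assert G[0, 1] == pytest.approx(G[1, 1], abs=1e-10)

    def test_monomorphic_only_panel_rejected(self):
        with pytest.raises(KinshipDataError):
            grm_unweighted(make_panel([[2, 0], [2, 0], [2, 0]]))

    def test_weighted_reduces_to_unweighted_for_constant_weights(self,
                                                                 small_dataset):
        _, panel, _, _ = small_dataset
        G0 = grm_unweighted(panel).values
        for w in (1.0, 0.5):
            weights = SnpWeights(list(panel.snp_ids),
                                 np.full(panel.n_snps, w))
            Gw = grm_weighted(panel, weights).values
            np.testing.assert_allclose(Gw, G0, atol=1e-10)

    def test_duplicated_snp_with_ld_weights_equals_dedup(self):
        """Down-weighting a duplicated SNP reproduces the deduplicated GRM."""
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        dup = np.column_stack([d, d[:, :1]])  # SNP 0 duplicated at the end
        cM = np.concatenate([np.arange(20) + 1.0, [1.000001]])
        order = np.argsort(cM)
        panel_dup = make_panel(dup[:, order], cM=cM[order])
        w = ld_weights(panel_dup, window_cM=0.5)
        G_dup = grm_weighted(panel_dup, w).values
        G_ref = grm_unweighted(make_panel(d)).values
        np.testing.assert_allclose(G_dup, G_ref, atol=1e-10)


class TestLdWeights:
    def test_uncorrelated_snps_get_unit_weight(self):
        d = np.array([[0, 0], [0, 2], [2, 0], [2, 2]])  # exactly uncorrelated
        w = ld_weights(make_panel(d), window_cM=10.0)
        np.testing.assert_allclose(w.weight, [1.0, 1.0], atol=1e-12)

    def test_duplicated_snp_weight_half(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]])
        w = ld_weights(make_panel(d), window_cM=10.0)
        np.testing.assert_allclose(w.weight, [0.5, 0.5], atol=1e-12)

    def test_correlated_block_matches_direct_summation(self):
        """Weights equal 1/(row sum of windowed r²) computed independently."""
        rng = np.random.default_rng(11)
        base = rng.integers(0, 3, size=200)
        block = np.column_stack([
            np.where(rng.random(200) < 0.9, base, rng.integers(0, 3, size=200))
            for _ in range(5)]).astype(np.int8)
        panel = make_panel(block, cM=np.linspace(1, 2, 5))
        w = ld_weights(panel, window_cM=5.0)
        r2 = np.corrcoef(block.T.astype(float)) ** 2
        expected = 1.0 / r2.sum(axis=1)
        np.testing.assert_allclose(w.weight, expected, atol=1e-10)

    def test_zero_variance_snp_excluded_with_warning(self):
        d = np.array([[0, 2, 1], [1, 2, 1], [2, 2, 0], [1, 2, 2]])
        with pytest.warns(UserWarning, match="zero-variance"):
            w = ld_weights(make_panel(d), window_cM=10.0)
        assert w.weight[1] == 1.0


class TestIbdMoment:
    def test_duplicate_genotypes_estimate_unity(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(1, 500))
        panel = make_panel(np.vstack([d, d,
                                      rng.integers(0, 3, size=(4, 500))]))
        K = ibd_moment_kinship(panel).values
        assert K[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_parent_offspring_near_half(self):
        cfg = SimulationConfig(n_families=12, generations=1, mean_sibship=3,
                               n_snps=4000, n_chromosomes=10,
                               ld_block_length_cM=0.0, seed=21)
        ped = simulate_pedigree(cfg)
        panel, _ = simulate_genotypes(ped, cfg)
        K = ibd_moment_kinship(panel).values
        child = next(r for r in ped.records if r.father_id is not None)
        ci = ped.index_of(child.individual_id)
        fi = ped.index_of(child.father_id)
        assert abs(K[ci, fi] - 0.5) < 0.05

    def test_too_few_individuals(self):
        with pytest.raises(KinshipDataError):
            ibd_moment_kinship(make_panel([[0, 1, 2]]))


class TestScaling:
    def test_normalize_arithmetic(self):
        K = RelationshipMatrix(["a", "b"], np.array([[4.0, 2.0], [2.0, 1.0]]),
                               "pedigree")
        np.testing.assert_allclose(normalize_diagonal(K).values,
                                   [[1, 1], [1, 1]], atol=1e-12)

    def test_normalize_idempotent_and_unit_diagonal(self):
        rng = np.random.default_rng(5)
        B = rng.normal(size=(8, 8))
        K = RelationshipMatrix([f"i{k}" for k in range(8)],
                               B @ B.T + 8 * np.eye(8), "grm_unweighted")
        K1 = normalize_diagonal(K)
        K2 = normalize_diagonal(K1)
        assert np.all(np.diag(K1.values) == 1.0)
        np.testing.assert_allclose(K1.values, K2.values, atol=1e-12)
        np.testing.assert_allclose(K1.values, K1.values.T, atol=1e-12)

    def test_repair_psd_clips_negative_eigenvalues(self):
        K = RelationshipMatrix(["a", "b"], np.array([[1.0, 1.2], [1.2, 1.0]]),
                               "grm_unweighted")
        R = repair_psd(K)
        vals = np.linalg.eigvalsh(R.values)
        assert vals.min() == pytest.approx(0.0, abs=1e-12)

    def test_repair_psd_noop_on_psd_input(self):
        rng = np.random.default_rng(6)
        B = rng.normal(size=(6, 6))
        K = RelationshipMatrix([f"i{k}" for k in range(6)], B @ B.T,
                               "grm_unweighted")
        np.testing.assert_allclose(repair_psd(K).values, K.values, atol=1e-10)

    def test_repair_psd_is_nearest_clipped_reconstruction(self):
        rng = np.random.default_rng(7)
        S = rng.normal(size=(10, 10))
        S = (S + S.T) / 2
        K = RelationshipMatrix([f"i{k}" for k in range(10)], S, "ibd_moment")
        R = repair_psd(K).values
        vals, vecs = np.linalg.eigh(S)
        direct = (vecs * np.maximum(vals, 0.0)) @ vecs.T
        np.testing.assert_allclose(R, direct, atol=1e-10)


class TestProperties:
    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_permutation_equivariance(self, seed):
        cfg = SimulationConfig(n_families=3, generations=1, mean_sibship=2,
                               n_snps=120, n_chromosomes=2, seed=seed)
        ped = simulate_pedigree(cfg)
        panel, _ = simulate_genotypes(ped, cfg)
        rng = np.random.default_rng(seed + 1)
        perm = rng.permutation(len(ped))
        panel_p = GenotypePanel([panel.individual_ids[i] for i in perm],
                                list(panel.snp_ids), panel.dosage[perm],
                                panel.chromosome, panel.cM, panel.bp,
                                panel.allele_freq)
        for build in (grm_unweighted, ibd_moment_kinship):
            K = build(panel).values
            Kp = build(panel_p).values
            np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-9)
        A = pedigree_relationship(ped)
        np.testing.assert_allclose(
            A.reorder([panel.individual_ids[i] for i in perm]).values,
            A.values[np.ix_(perm, perm)], atol=0)

    def test_genomic_estimates_track_pedigree(self, small_dataset):
        """GRM and moment-IBD agree with pedigree A up to sampling noise."""
        ped, _, _, _ = small_dataset
        cfg = SimulationConfig(n_families=8, generations=2, mean_sibship=3,
                               n_snps=5000, n_chromosomes=10,
                               ld_block_length_cM=0.0, seed=42)
        panel, _ = simulate_genotypes(ped, cfg)
        A = pedigree_relationship(ped).values
        for build in (grm_unweighted, ibd_moment_kinship):
            G = build(panel).values
            iu = np.triu_indices_from(A, k=1)
            assert np.mean(np.abs(G[iu] - A[iu])) < 0.05

    def test_mean_gene_drop_share_matches_pedigree(self, small_dataset):
        """Genome-average realized IBD ≈ expected additive relationship."""
        ped, _, ibd, _ = small_dataset
        A = pedigree_relationship(ped).values
        M = ibd.mean_share_matrix(np.arange(0, 400, 8))
        iu = np.triu_indices_from(A, k=1)
        related = A[iu] > 0
        assert np.mean(np.abs(M[iu] - A[iu])) < 0.06
        assert abs(np.mean(M[iu][related] - A[iu][related])) < 0.05
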