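"""Pedigree, genomic and combined relationship matrices."""

import numpy as np
import pytest
from scipy import sparse

from gxeblup.relationships import (
    GenotypeMatrix,
    HInverseParts,
    blend_and_invert,
    build_A,
    build_A_inverse,
    build_G_vanraden1,
    build_H_inverse,
    inbreeding_coefficients,
    make_h_inverse_parts,
    qc_genotypes,
)
from gxeblup.pedigree import Pedigree

from conftest import random_pedigree


class TestNumeratorMatrix:
    def test_unrelated_pair_is_identity(self, founder_pair):
        assert np.allclose(build_A(founder_pair), np.eye(2))

    def test_full_sibs_share_half(self, full_sib_pedigree):
        A = build_A(full_sib_pedigree)
        assert A[2, 3] == pytest.approx(0.5)

    def test_offspring_of_full_sibs_is_inbred(self, full_sib_pedigree):
        # tabular method by hand: F = 0.5 * a(sibs) = 0.25 -> diagonal 1.25
        A = build_A(full_sib_pedigree)
        assert A[4, 4] == pytest.approx(1.25)
        assert inbreeding_coefficients(full_sib_pedigree)[4] == pytest.approx(0.25)

    def test_subset_returns_principal_submatrix(self, full_sib_pedigree):
        A = build_A(full_sib_pedigree)
        sub = build_A(full_sib_pedigree, subset=[2, 4])
        assert np.allclose(sub, A[np.ix_([2, 4], [2, 4])])

    def test_diagonal_at_least_one_and_psd(self):
        ped = random_pedigree(120, seed=5)
        A = build_A(ped)
        assert np.all(np.diag(A) >= 1.0 - 1e-12)
        assert np.linalg.eigvalsh(A).min() > -1e-10

    def test_ordering_violation_raises(self):
        with pytest.raises(ValueError, match="topologically"):
            Pedigree(
                ids=[1, 2], sire=[1, -1], dam=[-1, -1],
                sex=["M", "F"], time_step=[0, 0],
            ).validate()


class TestAInverse:
    def test_founders_only_is_identity(self):
        ped = Pedigree(ids=[1, 2, 3], sire=[-1] * 3, dam=[-1] * 3,
                       sex=["M", "F", "M"], time_step=[0] * 3)
        assert np.allclose(build_A_inverse(ped).toarray(), np.eye(3))

    def test_single_known_parent_four_thirds_rule(self):
        # Henderson's rules by hand: inv([[1, .5], [.5, 1]]) has diagonal 4/3
        ped = Pedigree(ids=[1, 2], sire=[-1, 0], dam=[-1, -1],
                       sex=["M", "M"], time_step=[0, 1])
        ainv = build_A_inverse(ped).toarray()
        assert ainv[1, 1] == pytest.approx(4.0 / 3.0)
        assert ainv[0, 1] == pytest.approx(-2.0 / 3.0)

    @pytest.mark.parametrize("n,seed", [(40, 0), (300, 1), (500, 2)])
    def test_matches_dense_inverse(self, n, seed):
        ped = random_pedigree(n, seed=seed)
        A = build_A(ped)
        ainv = build_A_inverse(ped).toarray()
        assert np.abs(ainv @ A - np.eye(n)).max() < 1e-8

    def test_invariant_to_consistent_relabelling(self):
        ped = random_pedigree(60, seed=3)
        relabeled = Pedigree(
            ids=ped.ids * 7 + 3, sire=ped.sire, dam=ped.dam,
            sex=ped.sex, time_step=ped.time_step,
        )
        assert np.allclose(
            build_A_inverse(ped).toarray(), build_A_inverse(relabeled).toarray()
        )


class TestGenotypeQC:
    def _geno(self, M):
        M = np.asarray(M, float)
        return GenotypeMatrix(
            ids=np.arange(1, M.shape[0] + 1),
            snp_ids=np.array([f"SNP{j}" for j in range(M.shape[1])]),
            dosages=M,
        )

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        M = rng.binomial(2, 0.3, size=(30, 10)).astype(float)
        out = qc_genotypes(self._geno(M))
        assert out.dosages.shape == (30, 10)
        assert np.array_equal(out.dosages, M)

    def test_monomorphic_snp_removed(self):
        rng = np.random.default_rng(1)
        M = rng.binomial(2, 0.4, size=(20, 5)).astype(float)
        M[:, 2] = 2.0
        out = qc_genotypes(self._geno(M))
        assert out.n_snps == 4
        assert "SNP2" not in out.snp_ids

    def test_filters_apply_in_order(self):
        # 5 animals x 4 SNPs; animal 0 misses 2 of 4 dosages (call rate 0.5)
        M = np.array(
            [
                [np.nan, np.nan, 1, 1],
                [0, 1, 1, 2],
                [1, 1, 0, 1],
                [2, 0, 1, 0],
                [1, 2, 2, 1],
            ],
            float,
        )
        out = qc_genotypes(self._geno(M), snp_missing_max=0.5,
                           animal_callrate_min=0.95, maf_min=0.01)
        # hand filter: no SNP exceeds 50% missing; animal 1 dropped; all SNPs
        # stay polymorphic among the survivors
        assert list(out.ids) == [2, 3, 4, 5]
        assert out.n_snps == 4
        assert not np.isnan(out.dosages).any()

    def test_all_snps_removed_raises(self):
        M = np.full((4, 2), 2.0)
        with pytest.raises(ValueError, match="no SNPs"):
            qc_genotypes(self._geno(M))

    def test_missing_entries_mean_imputed(self):
        M = np.array([[0, 1], [2, 1], [np.nan, 1], [2, np.nan]], float)
        out = qc_genotypes(self._geno(M), snp_missing_max=0.5,
                           animal_callrate_min=0.4, maf_min=0.01)
        assert not np.isnan(out.dosages).any()


class TestGenomicMatrix:
    def test_hand_computed_two_animal_case(self):
        geno = GenotypeMatrix(
            ids=[1, 2], snp_ids=["a", "b"],
            dosages=np.array([[0.0, 2.0], [2.0, 0.0]]),
        )
        G = build_G_vanraden1(geno)
        # p = (0.5, 0.5); Z = [[-1, 1], [1, -1]]; denom = 2 * 0.5 = 1
        assert np.allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicate_animals_have_equal_rows(self):
        rng = np.random.default_rng(2)
        M = rng.binomial(2, 0.3, size=(6, 50)).astype(float)
        M[3] = M[0]
        G = build_G_vanraden1(GenotypeMatrix(np.arange(6), np.arange(50), M))
        assert np.allclose(G[0], G[3])
        assert G[0, 0] == pytest.approx(G[3, 3])

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(3)
        M = rng.binomial(2, 0.35, size=(12, 80)).astype(float)
        G1 = build_G_vanraden1(GenotypeMatrix(np.arange(12), np.arange(80), M))
        G2 = build_G_vanraden1(GenotypeMatrix(np.arange(12), np.arange(80), 2.0 - M))
        assert np.allclose(G1, G2)

    def test_monomorphic_matrix_raises(self):
        M = np.full((4, 3), 1.0) * np.array([0, 2, 0])
        with pytest.raises(ValueError, match="monomorphic"):
            build_G_vanraden1(GenotypeMatrix(np.arange(4), np.arange(3), M))

    def test_mean_diagonal_near_one_under_hw(self):
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.1, 0.5, 400)
        M = rng.binomial(2, freqs, size=(250, 400)).astype(float)
        G = build_G_vanraden1(GenotypeMatrix(np.arange(250), np.arange(400), M))
        assert abs(np.diag(G).mean() - 1.0) < 0.05


class TestBlendingAndH:
    def test_omega_limits(self):
        G = np.array([[1.2, 0.3], [0.3, 0.9]])
        A22 = np.eye(2)
        gw, _, _ = blend_and_invert(G, A22, omega=1.0)
        assert np.allclose(gw, A22)
        gw, _, _ = blend_and_invert(G, A22, omega=0.0)
        assert np.allclose(gw, G)

    def test_hand_blend(self):
        G = np.array([[2.0, -2.0], [-2.0, 2.0]])
        gw, _, _ = blend_and_invert(G + 0.05 * np.eye(2), np.eye(2), omega=0.01)
        expected = 0.99 * (G + 0.05 * np.eye(2)) + 0.01 * np.eye(2)
        assert np.allclose(gw, expected)

    def test_singular_blend_reports_condition(self):
        G = np.ones((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="condition"):
            blend_and_invert(G, np.zeros((2, 2)), omega=0.0)

    def test_empty_genotyped_set_gives_a_inverse(self):
        ped = random_pedigree(30, seed=7)
        a_inv = build_A_inverse(ped)
        parts = HInverseParts(
            a_inv=a_inv, geno_idx=np.empty(0, int),
            a22=np.empty((0, 0)), a22_inv=np.empty((0, 0)),
            g_w=np.empty((0, 0)), g_w_inv=np.empty((0, 0)), omega=0.01,
        )
        assert (build_H_inverse(parts) - a_inv).nnz == 0

    def test_gw_equal_a22_cancels_exactly(self):
        ped = random_pedigree(30, seed=8)
        a_inv = build_A_inverse(ped)
        idx = np.arange(10, 20)
        a22 = build_A(ped, subset=idx)
        a22_inv = np.linalg.inv(a22)
        parts = HInverseParts(
            a_inv=a_inv, geno_idx=idx, a22=a22, a22_inv=a22_inv,
            g_w=a22, g_w_inv=a22_inv, omega=0.01,
        )
        h_inv = build_H_inverse(parts)
        assert np.abs((h_inv - a_inv).toarray()).max() < 1e-10

    def test_matches_dense_textbook_h(self):
        """H assembled by the non-inverse partitioned formula, inverted
        densely, equals the sparse H-inverse (20 animals, 8 genotyped)."""
        ped = random_pedigree(20, seed=9, n_founders=6)
        rng = np.random.default_rng(10)
        freqs = rng.uniform(0.2, 0.5, 300)
        from gxeblup.synthetic_data import _drop_genotypes

        M = _drop_genotypes(rng, ped, freqs)
        idx = np.arange(12, 20)
        geno = GenotypeMatrix(ped.ids[idx], np.arange(300), M[idx])
        parts = make_h_inverse_parts(ped, geno, omega=0.05)
        h_inv = build_H_inverse(parts).toarray()

        A = build_A(ped)
        non = np.setdiff1d(np.arange(20), idx)
        order = np.r_[non, idx]
        A11 = A[np.ix_(non, non)]
        A12 = A[np.ix_(non, idx)]
        A22 = A[np.ix_(idx, idx)]
        A22i = np.linalg.inv(A22)
        Gw = parts.g_w
        H = np.zeros((20, 20))
        H[np.ix_(non, non)] = A11 + A12 @ A22i @ (Gw - A22) @ A22i @ A12.T
        H[np.ix_(non, idx)] = A12 @ A22i @ Gw
        H[np.ix_(idx, non)] = H[np.ix_(non, idx)].T
        H[np.ix_(idx, idx)] = Gw
        assert np.abs(np.linalg.inv(H) - h_inv).max() < 1e-8

    def test_index_misalignment_raises(self):
        ped = random_pedigree(10, seed=11)
        a_inv = build_A_inverse(ped)
        parts = HInverseParts(
            a_inv=a_inv, geno_idx=np.array([5, 25]),
            a22=np.eye(2), a22_inv=np.eye(2),
            g_w=np.eye(2), g_w_inv=np.eye(2), omega=0.01,
        )
        with pytest.raises(IndexError):
            build_H_inverse(parts)


def test_permutation_invariance_of_A():
    """Reordering founders (keeping topological order) permutes A."""
    ped = random_pedigree(50, seed=12)
    # swap the first two founders
    perm = np.arange(50)
    perm[[0, 1]] = [1, 0]
    inv = np.argsort(perm)
    ped2 = Pedigree(
        ids=ped.ids[perm],
        sire=np.where(ped.sire[perm] >= 0, inv[ped.sire[perm]], -1),
        dam=np.where(ped.dam[perm] >= 0, inv[ped.dam[perm]], -1),
        sex=ped.sex[perm],
        time_step=ped.time_step[perm],
    )
    A1 = build_A(ped)
    A2 = build_A(ped2)
    assert np.allclose(A2, A1[np.ix_(perm, perm)])
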