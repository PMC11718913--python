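"""Pedigree and genomic relationship matrices against dense/path-counting
oracles."""

import numpy as np
import pandas as pd
import pytest

from ssgblup.relmat import (PedigreeError, PedigreeTable, blend_and_tune_G,
                            build_A, build_A22, build_A_inverse, build_G,
                            build_H_inverse, qc_genotypes, relationship_set)

from conftest import random_pedigree, toy_genotypes


class TestPedigree:
    def test_reorders_parents_first(self):
        ped = PedigreeTable([3, 1, 2], [1, 0, 1], [2, 0, 0])
        pos = {a: i for i, a in enumerate(ped.ids)}
        assert pos[3] > pos[1] and pos[3] > pos[2]

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            PedigreeTable([1, 2], [2, 1], [0, 0])

    def test_unknown_parent_codes(self):
        ped = PedigreeTable([1, 2, 3], [0, None, 1], [float("nan"), 0, 2])
        assert (ped.sire[:2] == -1).all() and (ped.dam[:2] == -1).all()


class TestBuildA:
    def test_founders_identity(self):
        ped = PedigreeTable(list(range(1, 6)), [0] * 5, [0] * 5)
        assert np.array_equal(build_A(ped), np.eye(5))

    def test_trio(self, trio):
        A = build_A(trio)
        off = trio.index_of([3])[0]
        s = trio.index_of([1])[0]
        assert A[off, s] == 0.5
        assert A[off, off] == 1.0

    def test_full_sibs_and_inbred_offspring(self, full_sib_pedigree):
        # path counting: full sibs share each parent's allele path with
        # coefficient 1/4 + 1/4 = 1/2; their offspring has F = a_sibs/2
        A = build_A(full_sib_pedigree)
        i3, i4, i5 = full_sib_pedigree.index_of([3, 4, 5])
        assert A[i3, i4] == 0.5
        assert A[i5, i5] == 1.25
        assert full_sib_pedigree.inbreeding[i5] == 0.25


class TestInbreeding:
    def test_founder_zero(self, trio):
        assert trio.inbreeding[trio.index_of([1])[0]] == 0.0

    def test_parent_offspring_mating(self):
        # offspring of a dam mated to her own sire: F = a(sire, dam)/2 = 0.25
        ped = PedigreeTable([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 2, 3])
        assert ped.inbreeding[ped.index_of([4])[0]] == 0.25

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_tabular_diagonal(self, seed):
        ped = random_pedigree(50, seed)
        np.testing.assert_allclose(ped.inbreeding, np.diag(build_A(ped)) - 1,
                                   atol=1e-12)


class TestAInverse:
    def test_founders_identity(self):
        ped = PedigreeTable([1, 2, 3], [0] * 3, [0] * 3)
        assert np.array_equal(build_A_inverse(ped).toarray(), np.eye(3))

    def test_trio_known_pattern(self, trio):
        # dense inverse of the trio A gives diagonal (1.5, 1.5, 2.0)
        Ainv = build_A_inverse(trio).toarray()
        order = trio.index_of([1, 2, 3])
        np.testing.assert_allclose(np.diag(Ainv)[order], [1.5, 1.5, 2.0])

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_product_is_identity(self, seed):
        ped = random_pedigree(50, seed)
        prod = build_A(ped) @ build_A_inverse(ped).toarray()
        assert np.abs(prod - np.eye(50)).max() < 1e-8

    @pytest.mark.parametrize("seed", [7, 8])
    def test_A_positive_semidefinite(self, seed):
        ped = random_pedigree(40, seed)
        assert np.linalg.eigvalsh(build_A(ped)).min() >= -1e-10


class TestQC:
    def test_low_callrate_marker_removed(self):
        codes = np.tile([0.0, 1.0, 2.0, 1.0], (8, 1))
        codes[:4, 0] = np.nan  # 50% missing
        geno = toy_genotypes(codes)
        out, rep = qc_genotypes(geno)
        assert "m0" not in out.marker_ids
        assert rep.n_dropped_callrate == 1

    def test_maf_exactly_at_threshold_removed(self):
        # MAF must be strictly greater than 0.05
        codes = np.zeros((10, 2))
        codes[0, 0] = 1.0          # p = 0.05 exactly
        codes[:5, 1] = 1.0         # p = 0.25, keeps QC from emptying
        out, rep = qc_genotypes(toy_genotypes(codes))
        assert list(out.marker_ids) == ["m1"]
        assert rep.n_dropped_maf == 1

    def test_clean_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        codes = rng.binomial(2, 0.5, size=(40, 20)).astype(float)
        out, rep = qc_genotypes(toy_genotypes(codes))
        assert rep.n_markers_after == 20 and rep.n_animals_after == 40
        assert rep.n_missing_imputed == 0
        assert np.array_equal(out.codes, codes)

    def test_missing_imputed_to_marker_mean(self):
        rng = np.random.default_rng(6)
        codes = rng.binomial(2, 0.4, size=(10, 30)).astype(float)
        codes[0, 2] = np.nan  # one missing call: animal call rate stays high
        out, rep = qc_genotypes(toy_genotypes(codes))
        assert rep.n_animals_after == 10 and rep.n_missing_imputed == 1
        p = np.nanmean(codes[:, 2]) / 2
        assert out.codes[0, 2] == pytest.approx(2 * p)

    def test_all_markers_removed_errors(self):
        codes = np.zeros((10, 2))  # monomorphic: MAF 0
        with pytest.raises(ValueError, match="all markers removed"):
            qc_genotypes(toy_genotypes(codes))


class TestG:
    def test_single_marker_hand_computation(self):
        # two animals both code 0, one code 2 -> p = 1/3; by hand:
        # W = (-2/3, -2/3, 4/3), denom = 2*(1/3)(2/3) = 4/9
        codes = np.array([[0.0], [0.0], [2.0]])
        G = build_G(toy_genotypes(codes))
        W = codes[:, 0] - 2 / 3
        expect = np.outer(W, W) / (4 / 9)
        np.testing.assert_allclose(G, expect)

    def test_all_homozygous_p_half_diag_two(self):
        # one marker, codes 0 and 2 with p = 0.5: diag = 1 / (2*0.25) * 1 = 2
        codes = np.array([[0.0], [2.0]])
        G = build_G(toy_genotypes(codes))
        np.testing.assert_allclose(np.diag(G), [2.0, 2.0])

    def test_identical_twin_rows(self):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 3, size=(5, 50)).astype(float)
        codes[1] = codes[0]
        G = build_G(toy_genotypes(codes))
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])

    def test_hwe_mean_diagonal_near_one(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.5, size=2000)
        codes = rng.binomial(2, p, size=(200, 2000)).astype(float)
        G = build_G(toy_genotypes(codes, chrom=np.ones(2000, int),
                                  pos=np.arange(1, 2001)))
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_denominator_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            build_G(toy_genotypes(np.full((4, 3), 2.0)))


class TestBlend:
    def test_beta_one_returns_A22(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 40))
        G = X @ X.T / 40
        A22 = np.eye(6)
        np.testing.assert_allclose(blend_and_tune_G(G, A22, blend_beta=1.0),
                                   A22, atol=1e-12)

    def test_beta_zero_pd_input_unchanged(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 40))
        G = X @ X.T / 40
        out = blend_and_tune_G(G, np.eye(6), blend_beta=0.0, tune=False)
        np.testing.assert_allclose(out, 0.5 * (G + G.T))

    def test_singular_G_blended_to_pd(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 3))   # rank 3 < 8 animals
        G = X @ X.T / 3
        out = blend_and_tune_G(G, np.eye(8), blend_beta=0.05, tune=False)
        assert np.linalg.eigvalsh(out).min() > 0


class TestHInverse:
    def test_empty_genotyped_set(self, full_sib_pedigree):
        Ainv = build_A_inverse(full_sib_pedigree)
        Hinv = build_H_inverse(Ainv, None, None, [])
        np.testing.assert_allclose(Hinv.toarray(), Ainv.toarray())

    def test_G_equals_A22_cancels(self):
        ped = random_pedigree(12, 9)
        Ainv = build_A_inverse(ped)
        A22 = build_A22(ped, ped.ids[-4:])
        idx = ped.index_of(ped.ids[-4:])
        Hinv = build_H_inverse(Ainv, np.linalg.inv(A22), A22, idx)
        np.testing.assert_allclose(Hinv.toarray(), Ainv.toarray(), atol=1e-10)

    def test_matches_dense_H_oracle(self):
        # closed form of H: A modified so the genotyped block becomes G*
        ped = random_pedigree(10, 10)
        gids = ped.ids[-4:]
        idx = ped.index_of(gids)
        rest = np.setdiff1d(np.arange(10), idx)
        A = build_A(ped)
        A22 = A[np.ix_(idx, idx)]
        rng = np.random.default_rng(11)
        X = rng.normal(size=(4, 200))
        G = 0.8 * (X @ X.T / 200) + 0.2 * A22   # PD, A22-like scale

        A11, A12 = A[np.ix_(rest, rest)], A[np.ix_(rest, idx)]
        A22i = np.linalg.inv(A22)
        H = np.zeros_like(A)
        H[np.ix_(rest, rest)] = A11 + A12 @ A22i @ (G - A22) @ A22i @ A12.T
        H[np.ix_(rest, idx)] = A12 @ A22i @ G
        H[np.ix_(idx, rest)] = H[np.ix_(rest, idx)].T
        H[np.ix_(idx, idx)] = G

        Hinv = build_H_inverse(build_A_inverse(ped), A22i, G, idx)
        assert np.abs(Hinv.toarray() - np.linalg.inv(H)).max() < 1e-8

    def test_relationship_set_id_mismatch(self, small_dataset):
        geno = small_dataset["geno"]
        bad = geno
        bad.ids = bad.ids.copy()
        bad.ids[0] = "not_in_pedigree"
        with pytest.raises(PedigreeError, match="not in pedigree"):
            relationship_set(small_dataset["ped"], bad)


from hypothesis import given, settings, strategies as st


@st.composite
def pedigrees(draw):
    """Arbitrary valid pedigree: parents drawn among earlier animals."""
    n = draw(st.integers(min_value=2, max_value=25))
    sire, dam = [], []
    for i in range(n):
        if i < 2 or draw(st.booleans()):
            sire.append(0)
            dam.append(0)
        else:
            s = draw(st.integers(min_value=1, max_value=i))
            d = draw(st.integers(min_value=1, max_value=i))
            sire.append(s)
            dam.append(d if d != s else 0)
    return PedigreeTable(list(range(1, n + 1)), sire, dam)


@given(pedigrees())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_pedigree_matrix_invariants(ped):
    """A is PSD with diagonal 1 + F in [1, 2), and Henderson's sparse
    inverse actually inverts the tabular A."""
    A = build_A(ped)
    F = ped.inbreeding
    np.testing.assert_allclose(np.diag(A), 1.0 + F, atol=1e-12)
    assert np.all((F >= 0) & (F < 1))
    assert np.linalg.eigvalsh(A).min() >= -1e-10
    n = len(ped)
    assert np.abs(A @ build_A_inverse(ped).toarray() - np.eye(n)).max() < 1e-8


def test_A22_consistent_with_subset_of_A(small_dataset):
    ped, geno = small_dataset["ped"], small_dataset["geno"]
    idx = ped.index_of(geno.ids)
    np.testing.assert_allclose(build_A22(ped, geno.ids),
                               build_A(ped)[np.ix_(idx, idx)])
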