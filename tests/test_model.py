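"""Mixed-model equations against GLS/OLS oracles; accuracy and rankings."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ssgblup.model import (SolutionSet, assemble_mme, build_design, evaluate,
                           infer_roles, prediction_accuracy, solve_mme,
                           summarize_rankings)
from ssgblup.relmat import PedigreeTable, build_A, build_A_inverse
from ssgblup.varcomp import VarianceComponents


def make_vc(h=10.0, u=20.0, p=15.0, e=50.0) -> VarianceComponents:
    return VarianceComponents(herd_year=h, additive=u, perm_env=p, residual=e)


def tiny_pheno() -> pd.DataFrame:
    # 8 records on 3 cows (animals 4..6 of a 6-animal pedigree)
    return pd.DataFrame({
        "cow_id": [4, 4, 4, 5, 5, 5, 6, 6],
        "parity": [1, 2, 3, 1, 2, 3, 1, 2],
        "breed_group": [1, 1, 1, 2, 2, 2, 3, 3],
        "herd_year": ["h1", "h1", "h2", "h2", "h1", "h2", "h1", "h2"],
        "year_month": ["m1", "m2", "m2", "m1", "m1", "m2", "m1", "m1"],
        "days_open": [97.0, 103.0, 101.0, 91.0, 95.0, 94.0, 88.0, 92.0],
    })


def tiny_ped() -> PedigreeTable:
    return PedigreeTable([1, 2, 3, 4, 5, 6],
                         [0, 0, 0, 1, 1, 3],
                         [0, 0, 0, 2, 2, 2])


class TestBuildDesign:
    def test_block_row_sums(self):
        design = build_design(tiny_pheno(), tiny_ped())
        for M in (design.Q, design.Z, design.W):
            np.testing.assert_array_equal(M.sum(axis=1).A1, 1.0)

    def test_repeated_records_column_sums(self):
        design = build_design(tiny_pheno(), tiny_ped())
        w4 = design.W[:, list(design.cow_ids).index(4)]
        z4 = design.Z[:, list(design.animal_ids).index(4)]
        assert w4.sum() == 3 and z4.sum() == 3

    def test_breed_group_reference_constraint(self):
        design = build_design(tiny_pheno(), tiny_ped())
        bg_cols = [n for n in design.fixed_names if n.startswith("breed_group")]
        assert len(bg_cols) == 2                       # 3 levels, 1 reference
        assert "breed_group=2" not in design.fixed_names   # default reference

    def test_cow_missing_from_pedigree(self):
        pheno = tiny_pheno()
        pheno.loc[0, "cow_id"] = 99
        with pytest.raises(ValueError, match="not in pedigree"):
            build_design(pheno, tiny_ped())

    def test_ancestor_columns_all_zero(self):
        design = build_design(tiny_pheno(), tiny_ped())
        z1 = design.Z[:, list(design.animal_ids).index(1)]
        assert z1.sum() == 0


class TestSolveMME:
    def test_matches_dense_gls_oracle(self):
        pheno, ped = tiny_pheno(), tiny_ped()
        vc = make_vc()
        design = build_design(pheno, ped)
        A = build_A(ped)
        y = pheno["days_open"].to_numpy()
        X = design.X.toarray()
        Q, Z, W = design.Q.toarray(), design.Z.toarray(), design.W.toarray()
        V = (Q @ Q.T * vc.herd_year + Z @ A @ Z.T * vc.additive
             + W @ W.T * vc.perm_env + np.eye(len(y)) * vc.residual)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - X @ b
        u = vc.additive * A @ Z.T @ Vi @ resid
        h = vc.herd_year * Q.T @ Vi @ resid
        p = vc.perm_env * W.T @ Vi @ resid

        mme = assemble_mme(design, sparse.csr_matrix(build_A_inverse(ped)), vc)
        sols = solve_mme(mme, y)
        np.testing.assert_allclose(sols.fixed.to_numpy(), b, atol=1e-8)
        np.testing.assert_allclose(sols.ebv.to_numpy(), u, atol=1e-8)
        np.testing.assert_allclose(sols.herd_year.to_numpy(), h, atol=1e-8)
        np.testing.assert_allclose(sols.perm_env.to_numpy(), p, atol=1e-8)

    def test_ols_limit_with_negligible_random_variances(self):
        pheno, ped = tiny_pheno(), tiny_ped()
        vc = make_vc(h=1e-8, u=1e-8, p=1e-8, e=1.0)
        design = build_design(pheno, ped)
        mme = assemble_mme(design, build_A_inverse(ped), vc)
        y = pheno["days_open"].to_numpy()
        sols = solve_mme(mme, y)
        X = design.X.toarray()
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(sols.fixed.to_numpy(), b_ols, atol=1e-4)

    def test_shrinkage_limit_small_additive_variance(self):
        pheno, ped = tiny_pheno(), tiny_ped()
        vc = make_vc(u=1e-10)
        design = build_design(pheno, ped)
        mme = assemble_mme(design, build_A_inverse(ped), vc)
        sols = solve_mme(mme, pheno["days_open"].to_numpy())
        assert np.abs(sols.ebv.to_numpy()).max() < 1e-6

    def test_direct_vs_pcg(self, small_dataset):
        ped, pheno = small_dataset["ped"], small_dataset["pheno"]
        vc = make_vc(30.41, 18.23, 51.19, 707.87)
        design = build_design(pheno, ped)
        mme = assemble_mme(design, build_A_inverse(ped), vc)
        y = pheno["days_open"].to_numpy()
        direct = solve_mme(mme, y, method="direct")
        pcg = solve_mme(mme, y, method="pcg", tol=1e-12)
        np.testing.assert_allclose(pcg.ebv.to_numpy(), direct.ebv.to_numpy(),
                                   atol=1e-6)

    def test_record_permutation_invariance(self):
        pheno, ped = tiny_pheno(), tiny_ped()
        vc = make_vc()
        Ainv = build_A_inverse(ped)
        y_sols = []
        for order in (range(5), [3, 1, 4, 0, 2]):
            shuffled = pheno.iloc[list(order)].reset_index(drop=True)
            design = build_design(shuffled, ped)
            mme = assemble_mme(design, Ainv, vc)
            sols = solve_mme(mme, shuffled["days_open"].to_numpy())
            y_sols.append(sols.ebv.to_numpy())
        np.testing.assert_allclose(y_sols[0], y_sols[1], atol=1e-10)

    def test_kkt_stationarity(self):
        # X'e = 0 and, for each random block, T_i'e = lambda_i * Ginv u_i
        pheno, ped = tiny_pheno(), tiny_ped()
        vc = make_vc()
        design = build_design(pheno, ped)
        Ainv = build_A_inverse(ped)
        mme = assemble_mme(design, Ainv, vc)
        y = pheno["days_open"].to_numpy()
        s = solve_mme(mme, y)
        e = (y - design.X @ s.fixed.to_numpy() - design.Q @ s.herd_year.to_numpy()
             - design.Z @ s.ebv.to_numpy() - design.W @ s.perm_env.to_numpy())
        assert np.abs(design.X.T @ e).max() < 1e-6
        lam_u = vc.residual / vc.additive
        np.testing.assert_allclose(design.Z.T @ e,
                                   lam_u * (Ainv @ s.ebv.to_numpy()),
                                   atol=1e-6)

    def test_zero_variance_rejected(self):
        design = build_design(tiny_pheno(), tiny_ped())
        vc = VarianceComponents(herd_year=0.0, additive=1, perm_env=1,
                                residual=1)
        with pytest.raises(ValueError, match="must be > 0"):
            assemble_mme(design, build_A_inverse(tiny_ped()), vc)


class TestAccuracy:
    def test_zero_pev_gives_one(self):
        vc = make_vc()
        assert prediction_accuracy([0.0], vc, [0.0])[0] == 1.0

    def test_pev_equal_sigma_u_gives_zero(self):
        vc = make_vc()
        assert prediction_accuracy([vc.additive], vc, [0.0])[0] == 0.0

    def test_unconnected_founder_accuracy_zero(self):
        # an extra founder (7) with no records and no relatives
        ped = PedigreeTable([1, 2, 3, 7], [0, 0, 1, 0], [0, 0, 2, 0])
        pheno = pd.DataFrame({
            "cow_id": [3, 3, 3, 3], "parity": [1, 2, 1, 2],
            "breed_group": [1, 1, 1, 1],
            "herd_year": ["h1", "h1", "h2", "h2"],
            "year_month": ["m1", "m2", "m2", "m1"],
            "days_open": [95.0, 99.0, 93.0, 100.0]})
        vc = make_vc()
        sols = evaluate(pheno, ped, build_A_inverse(ped), vc)
        assert sols.accuracy.loc[7] == pytest.approx(0.0, abs=1e-6)
        assert sols.pev.loc[7] == pytest.approx(vc.additive, rel=1e-8)

    def test_parent_average_for_recordless_offspring(self):
        # no records, known parents, no descendants -> EBV = parent mean
        ped = PedigreeTable([1, 2, 3, 4], [0, 0, 0, 1], [0, 0, 0, 2])
        pheno = pd.DataFrame({
            "cow_id": [1, 2, 3], "parity": [1, 1, 1],
            "breed_group": [1, 2, 3], "herd_year": ["h1", "h2", "h1"],
            "year_month": ["m1", "m1", "m2"],
            "days_open": [90.0, 105.0, 99.0]})
        vc = make_vc()
        sols = evaluate(pheno, ped, build_A_inverse(ped), vc,
                        compute_pev=False)
        pa = 0.5 * (sols.ebv.loc[1] + sols.ebv.loc[2])
        assert sols.ebv.loc[4] == pytest.approx(pa, abs=1e-8)


class TestRankings:
    def _solutions(self, ped, values):
        return SolutionSet(
            fixed=pd.Series(dtype=float), herd_year=pd.Series(dtype=float),
            ebv=pd.Series(values, index=ped.ids),
            perm_env=pd.Series(dtype=float), single_step=False)

    def test_roles_inferred_from_pedigree(self):
        ped = tiny_ped()
        roles = infer_roles(ped)
        assert roles.loc[1] == "bull" and roles.loc[2] == "dam"
        assert roles.loc[4] == "unknown"

    def test_top_fraction_one_equals_full_mean(self):
        ped = tiny_ped()
        sols = self._solutions(ped, [1.0, -2.0, 0.5, 3.0, -1.0, 0.0])
        table = summarize_rankings(sols, tiny_pheno(), ped, top_fraction=1.0)
        allrow = table[(table.dataset == "all") & (table.breed_group == 0)]
        toprow = table[(table.dataset == "top20_all") & (table.breed_group == 0)]
        assert allrow["mean_value"].iloc[0] == toprow["mean_value"].iloc[0]

    def test_all_equal_values_tie(self):
        ped = tiny_ped()
        sols = self._solutions(ped, [1.5] * 6)
        table = summarize_rankings(sols, tiny_pheno(), ped)
        assert np.allclose(table["mean_value"], 1.5)

    def test_breed_group_effect_sign_structure(self):
        # the estimated breed-group fixed effects recover the simulated
        # sign structure (group 3 below the group-2 reference, group 1
        # above); effects scaled up so the ordering is resolvable at
        # desk-scale record counts
        from ssgblup.syndata import SimConfig, simulate_dataset
        cfg = SimConfig(n_cows_with_records=300, n_founders=40,
                        n_generations=2, parities_per_cow=(2, 4),
                        n_herd_years=10, n_year_months=6, n_snps=0,
                        bg_effects=(5.0, 0.0, -15.0), record_bounds=None,
                        seed=77)
        ped, _, pheno, _ = simulate_dataset(cfg, genotypes=False)
        vc = make_vc(30.41, 18.23, 51.19, 707.87)
        sols = evaluate(pheno, ped, build_A_inverse(ped), vc,
                        compute_pev=False)
        assert sols.fixed["breed_group=3"] < 0 < sols.fixed["breed_group=1"]
        table = summarize_rankings(sols, pheno, ped)
        assert set(table["dataset"]) >= {"all", "top20_all"}
        top = table[(table.dataset == "top20_all") & (table.breed_group == 0)]
        full = table[(table.dataset == "all") & (table.breed_group == 0)]
        assert top["mean_value"].iloc[0] <= full["mean_value"].iloc[0]
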