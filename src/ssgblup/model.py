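"""Repeatability animal model: design matrices, mixed-model equations,
breeding-value prediction, accuracy and ranking summaries.

The model is y = Xb + Qh + Zu + Wp + e with fixed effects b (breed
group, parity, year-month of calving) and random effects h (herd-year,
I sigma_h2), u (additive, A sigma_u2 or H sigma_u2 in single-step
mode), p (permanent environment, I sigma_p2) and e (I sigma_e2).
Henderson's mixed-model equations are solved either directly (which
also yields prediction error variances, PEV) or by Jacobi-preconditioned
conjugate gradients for larger systems. Accuracy is
sqrt(1 - PEV / ((1 + F) sigma_u2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import cg as sparse_cg, spsolve

from .relmat import PedigreeTable

logger = logging.getLogger(__name__)

FIXED_FACTORS = ("breed_group", "parity", "year_month")
#: default reference levels for the fixed-effect contrasts; breed group 2
#: is the reference so group effects read as deviations from the middle
#: Holstein-fraction class
DEFAULT_REFERENCES = {"breed_group": 2}


@dataclass
class DesignMatrices:
    """Sparse incidence matrices of the repeatability model."""

    X: sparse.csr_matrix          # records x fixed-effect columns
    Q: sparse.csr_matrix          # records x herd-year levels
    Z: sparse.csr_matrix          # records x all pedigree animals
    W: sparse.csr_matrix          # records x record cows
    fixed_names: list[str]
    herd_year_levels: np.ndarray
    animal_ids: np.ndarray
    cow_ids: np.ndarray

    @property
    def n_records(self) -> int:
        return self.X.shape[0]


def build_design(pheno: pd.DataFrame, ped: PedigreeTable,
                 references: dict | None = None) -> DesignMatrices:
    """Incidence matrices for the model, with reference-level constraints.

    X carries an intercept plus one-hot columns for each fixed factor
    with one level dropped (the reference; configurable, breed group
    defaults to level 2). Z spans every pedigree animal: ancestors
    without records get all-zero columns.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    missing = set(pheno["cow_id"]) - set(ped.ids)
    if missing:
        raise ValueError(f"cows not in pedigree: {sorted(missing)[:10]}")

    n = len(pheno)
    cols = [sparse.csr_matrix(np.ones((n, 1)))]
    names = ["intercept"]
    for factor in FIXED_FACTORS:
        levels = np.asarray(sorted(pheno[factor].unique()))
        ref = refs.get(factor, levels[0])
        if ref not in levels:
            ref = levels[0]
        for lev in levels:
            if lev == ref:
                continue
            cols.append(sparse.csr_matrix(
                (pheno[factor] == lev).to_numpy(float).reshape(-1, 1)))
            names.append(f"{factor}={lev}")
    X = sparse.hstack(cols, format="csr")

    hy_levels, hy_idx = np.unique(pheno["herd_year"], return_inverse=True)
    Q = _indicator(hy_idx, len(hy_levels))

    animal_pos = {a: i for i, a in enumerate(ped.ids)}
    z_idx = np.asarray([animal_pos[c] for c in pheno["cow_id"]])
    Z = _indicator(z_idx, len(ped.ids))

    cow_ids, w_idx = np.unique(pheno["cow_id"].to_numpy(object),
                               return_inverse=True)
    W = _indicator(w_idx, len(cow_ids))

    return DesignMatrices(X=X, Q=Q, Z=Z, W=W, fixed_names=names,
                          herd_year_levels=hy_levels, animal_ids=ped.ids.copy(),
                          cow_ids=cow_ids)


def _indicator(idx: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(idx)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, n_levels))


# ---------------------------------------------------------------------------
# Mixed-model equations
# ---------------------------------------------------------------------------


@dataclass
class MixedModelEquations:
    LHS: sparse.csc_matrix
    RHS: np.ndarray
    slices: dict                      # block name -> slice into equations
    design: DesignMatrices
    vc: "object"                      # VarianceComponents-like
    single_step: bool = False


def assemble_mme(design: DesignMatrices, rel_inv: sparse.spmatrix, vc,
                 single_step: bool = False) -> MixedModelEquations:
    """Henderson MME in variance-ratio form.

    LHS = T'T + blockdiag(0, I*lam_h, rel_inv*lam_u, I*lam_p) with
    T = [X Q Z W] and lam_x = sigma_e2 / sigma_x2; RHS = T'y is attached
    later by :func:`solve_mme` (the design holds no y). ``rel_inv`` is
    A^-1 for pedigree evaluation or H^-1 for single-step.
    """
    for name in ("herd_year", "additive", "perm_env", "residual"):
        if getattr(vc, name) <= 0:
            raise ValueError(f"variance component {name} must be > 0")
    T = sparse.hstack([design.X, design.Q, design.Z, design.W], format="csr")
    nx, nh = design.X.shape[1], design.Q.shape[1]
    nu, npe = design.Z.shape[1], design.W.shape[1]
    if rel_inv.shape != (nu, nu):
        raise ValueError("rel_inv dimension does not match pedigree size")
    lam_h = vc.residual / vc.herd_year
    lam_u = vc.residual / vc.additive
    lam_p = vc.residual / vc.perm_env
    penalty = sparse.block_diag([
        sparse.csr_matrix((nx, nx)),
        lam_h * sparse.eye(nh),
        lam_u * sparse.csr_matrix(rel_inv),
        lam_p * sparse.eye(npe),
    ], format="csr")
    LHS = (T.T @ T + penalty).tocsc()
    slices = {
        "fixed": slice(0, nx),
        "herd_year": slice(nx, nx + nh),
        "additive": slice(nx + nh, nx + nh + nu),
        "perm_env": slice(nx + nh + nu, nx + nh + nu + npe),
    }
    return MixedModelEquations(LHS=LHS, RHS=np.empty(0), slices=slices,
                               design=design, vc=vc, single_step=single_step)


@dataclass
class SolutionSet:
    """Solutions of one evaluation run."""

    fixed: pd.Series                  # named fixed-effect estimates, days
    herd_year: pd.Series
    ebv: pd.Series                    # per pedigree animal (EBV or GEBV)
    perm_env: pd.Series
    single_step: bool
    pev: pd.Series | None = None      # days^2, direct mode only
    accuracy: pd.Series | None = None
    solver_info: dict = field(default_factory=dict)

    @property
    def kind(self) -> str:
        return "GEBV" if self.single_step else "EBV"


def solve_mme(mme: MixedModelEquations, y: np.ndarray, method: str = "direct",
              tol: float = 1e-10, max_iter: int = 5000,
              compute_pev: bool = False) -> SolutionSet:
    """Solve the assembled equations.

    ``direct`` factorizes the sparse system (and, when ``compute_pev``,
    inverts it densely to get PEV = sigma_e2 * diag of the additive block
    of LHS^-1). ``pcg`` runs Jacobi-preconditioned conjugate gradients
    and cannot provide PEV.
    """
    d = mme.design
    T = sparse.hstack([d.X, d.Q, d.Z, d.W], format="csr")
    rhs = T.T @ np.asarray(y, float)
    pev = None
    if method == "direct":
        if compute_pev:
            dense = mme.LHS.toarray()
            c, low = cho_factor(dense, lower=True)
            sol = cho_solve((c, low), rhs)
            inv = cho_solve((c, low), np.eye(dense.shape[0]))
            pev = np.diag(inv)[mme.slices["additive"]] * mme.vc.residual
        else:
            sol = spsolve(mme.LHS, rhs)
        info = {"method": "direct"}
    elif method == "pcg":
        if compute_pev:
            raise ValueError("PEV requires the direct solver")
        M = sparse.diags(1.0 / mme.LHS.diagonal())
        sol, flag = sparse_cg(mme.LHS, rhs, rtol=tol, maxiter=max_iter, M=M)
        if flag != 0:
            res = np.linalg.norm(mme.LHS @ sol - rhs)
            raise RuntimeError(
                f"PCG did not converge in {max_iter} iterations "
                f"(residual norm {res:.3e})")
        info = {"method": "pcg", "tol": tol}
    else:
        raise ValueError(f"unknown solver {method!r}")

    sl = mme.slices
    out = SolutionSet(
        fixed=pd.Series(sol[sl["fixed"]], index=d.fixed_names),
        herd_year=pd.Series(sol[sl["herd_year"]], index=d.herd_year_levels),
        ebv=pd.Series(sol[sl["additive"]], index=d.animal_ids),
        perm_env=pd.Series(sol[sl["perm_env"]], index=d.cow_ids),
        single_step=mme.single_step,
        solver_info=info,
    )
    if pev is not None:
        out.pev = pd.Series(pev, index=d.animal_ids)
    return out


def prediction_accuracy(pev: np.ndarray, vc, F: np.ndarray,
                        rel_diag: np.ndarray | None = None) -> np.ndarray:
    """Theoretical accuracy sqrt(1 - PEV / (d_i sigma_u2)).

    d_i is the diagonal of the relationship matrix used in the
    evaluation: 1 + F under the pedigree A; pass ``rel_diag`` to use the
    single-step H diagonal (G* entries for genotyped animals) instead.
    Reduces to sqrt(1 - PEV/sigma_u2) for non-inbred animals; PEV beyond
    the additive variance (numerical noise) is clipped to accuracy 0.
    """
    if rel_diag is None:
        rel_diag = 1.0 + np.asarray(F, float)
    denom = np.asarray(rel_diag, float) * vc.additive
    ratio = np.asarray(pev, float) / denom
    if np.any(ratio > 1.001):
        logger.warning("PEV exceeds d_i*sigma_u2 for %d animals; clipping",
                       int((ratio > 1.001).sum()))
    return np.sqrt(np.clip(1.0 - ratio, 0.0, 1.0))


def evaluate(pheno: pd.DataFrame, ped: PedigreeTable, rel_inv, vc,
             single_step: bool = False, references: dict | None = None,
             method: str = "direct", compute_pev: bool = True,
             rel_diag: np.ndarray | None = None) -> SolutionSet:
    """Design + assemble + solve in one call; attaches accuracy when PEV
    is available. Pass ``rel_diag`` (e.g. the H diagonal from the
    relationship set) for correct single-step accuracies."""
    design = build_design(pheno, ped, references=references)
    mme = assemble_mme(design, rel_inv, vc, single_step=single_step)
    sols = solve_mme(mme, pheno["days_open"].to_numpy(float), method=method,
                     compute_pev=compute_pev and method == "direct")
    if sols.pev is not None:
        acc = prediction_accuracy(sols.pev.to_numpy(), vc, ped.inbreeding,
                                  rel_diag=rel_diag)
        sols.accuracy = pd.Series(acc, index=ped.ids)
    return sols


# ---------------------------------------------------------------------------
# Ranking summaries
# ---------------------------------------------------------------------------


def infer_roles(ped: PedigreeTable) -> pd.Series:
    """bull/dam/unknown per animal from pedigree appearance (an id in the
    sire column is a bull, in the dam column a dam)."""
    sires = {ped.ids[s] for s in ped.sire if s >= 0}
    dams = {ped.ids[d] for d in ped.dam if d >= 0}
    role = ["bull" if a in sires else "dam" if a in dams else "unknown"
            for a in ped.ids]
    return pd.Series(role, index=ped.ids)


def summarize_rankings(solutions: SolutionSet, pheno: pd.DataFrame,
                       ped: PedigreeTable, top_fraction: float = 0.20,
                       direction: str = "most_negative") -> pd.DataFrame:
    """Mean (G)EBV by breed group for each dataset and its top subset.

    Datasets are all animals, bulls and dams (roles inferred from the
    pedigree); the top subset keeps ``top_fraction`` of the dataset
    ranked by most-negative value (fewer days open = genetic advantage).
    Mean accuracy is included when available. Breed group per animal
    comes from the pedigree annotation or, failing that, the phenotypes.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    ebv = solutions.ebv
    if ped.breed_group is not None:
        bg = pd.Series([int(b) for b in ped.breed_group], index=ped.ids)
    else:
        bg = pheno.groupby("cow_id")["breed_group"].first().reindex(ebv.index)
    roles = infer_roles(ped)
    acc = solutions.accuracy

    datasets = {
        "all": ebv.index,
        "bulls": ebv.index[roles.reindex(ebv.index) == "bull"],
        "dams": ebv.index[roles.reindex(ebv.index) == "dam"],
    }
    rows = []
    for name, ids in datasets.items():
        if len(ids) == 0:
            logger.warning("ranking subset %r is empty; omitted", name)
            continue
        vals = ebv.loc[ids]
        k = max(1, int(round(top_fraction * len(vals))))
        ascending = direction == "most_negative"
        top = vals.sort_values(ascending=ascending).iloc[:k]
        for subset, sel in ((name, vals), (f"top20_{name}", top)):
            groups = bg.reindex(sel.index)
            for g in sorted(groups.dropna().unique()):
                sub = sel[groups == g]
                rows.append({
                    "dataset": subset, "breed_group": int(g), "n": len(sub),
                    "mean_value": sub.mean(),
                    "mean_accuracy": (acc.reindex(sub.index).mean()
                                      if acc is not None else np.nan),
                })
            rows.append({
                "dataset": subset, "breed_group": 0, "n": len(sel),
                "mean_value": sel.mean(),
                "mean_accuracy": (acc.reindex(sel.index).mean()
                                  if acc is not None else np.nan),
            })
    return pd.DataFrame(rows)
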