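"""Variance component estimation by average-information REML.

Estimates the four components of the repeatability animal model —
herd-year, additive, permanent environment and residual variance — under
either the pedigree relationship inverse A^-1 (AIREML) or the single-step
inverse H^-1 (ssGAIREML). Second-order updates use the average-information
matrix; any round proposing a non-positive component falls back to one
EM step, which is guaranteed to keep components positive and the REML
likelihood non-decreasing. Standard errors are sqrt(diag(AI^-1)) at
convergence.

All quantities are computed from the mixed-model equations: with
M the coefficient matrix in variance-ratio form and C = sigma_e2 * M^-1
the prediction-error covariance, the identities

    tr(P Z_i G_i Z_i') = (q_i - tr(G_i^-1 C_ii) / s_i) / s_i
    y'P Z_i G_i Z_i' P y = u_i' G_i^-1 u_i / s_i^2
    tr(P) = (n - rank(X) - sum_i (q_i - tr(G_i^-1 C_ii)/s_i)) / s_e

give the gradient, and working variates f_i = Z_i u_i / s_i (f_e = e/s_e)
give AI_ij = f_i' P f_j / 2. Traces use a dense factorization of M,
exact at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

from .model import DesignMatrices

logger = logging.getLogger(__name__)

COMPONENT_NAMES = ("herd_year", "additive", "perm_env", "residual")


class REMLError(RuntimeError):
    """AI-REML failed to converge."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class VarianceComponents:
    """The four variances (days^2) with standard errors and ratios."""

    herd_year: float
    additive: float
    perm_env: float
    residual: float
    se: dict = field(default_factory=dict)
    source: str = "AIREML"
    n_iterations: int = 0
    converged: bool = True

    @property
    def phenotypic(self) -> float:
        return self.herd_year + self.additive + self.perm_env + self.residual

    @property
    def h2(self) -> float:
        return heritability(self)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.herd_year, self.additive, self.perm_env, self.residual)

    def to_dict(self) -> dict:
        return {
            "herd_year": self.herd_year, "additive": self.additive,
            "perm_env": self.perm_env, "residual": self.residual,
            "se": dict(self.se), "h2": self.h2,
            "repeatability": repeatability(self), "source": self.source,
            "n_iterations": self.n_iterations, "converged": self.converged,
        }


def heritability(vc: VarianceComponents) -> float:
    """h2 = sigma_u2 / (sigma_h2 + sigma_u2 + sigma_p2 + sigma_e2).

    The denominator deliberately includes the herd-year variance, i.e.
    heritability is taken relative to the full phenotypic variance of a
    record including its herd-year component.
    """
    denom = vc.phenotypic
    if denom <= 0:
        raise ValueError("zero phenotypic variance")
    return vc.additive / denom


def repeatability(vc: VarianceComponents) -> float:
    """(sigma_u2 + sigma_p2) / phenotypic — upper bound on h2 and the
    expected correlation of repeated records of one cow across herd-years."""
    denom = vc.phenotypic
    if denom <= 0:
        raise ValueError("zero phenotypic variance")
    return (vc.additive + vc.perm_env) / denom


# ---------------------------------------------------------------------------
# Core engine over an arbitrary list of random terms
# ---------------------------------------------------------------------------


@dataclass
class _Term:
    name: str
    Z: sparse.csr_matrix
    Ginv: sparse.spmatrix | None      # None means identity


def reml_core(y: np.ndarray, X: sparse.spmatrix, terms: list,
              start: np.ndarray | None = None, tol: float = 1e-8,
              max_iter: int = 200, verbose: bool = False) -> dict:
    """AI-REML for y = Xb + sum_i Z_i u_i + e, u_i ~ N(0, G_i s_i).

    ``terms`` is a list of ``(name, Z, Ginv)`` with ``Ginv`` a sparse
    inverse covariance structure or None for identity. Returns a dict
    with components (named, residual last), SEs, the log-likelihood
    trajectory and iteration count.
    """
    y = np.asarray(y, float)
    X = sparse.csr_matrix(X)
    terms = [_Term(*t) for t in terms]
    n = len(y)
    p = X.shape[1]
    k = len(terms)

    # identity-covariance terms whose incidence has at most one nonzero
    # per row contribute a diagonal LHS block: absorb them so the dense
    # factorization covers only the fixed + structured-covariance core.
    # Terms are absorbed (largest first) only while their cross-products
    # with already-absorbed terms vanish, keeping the absorbed block
    # truly diagonal.
    eligible = sorted((i for i, t in enumerate(terms)
                       if t.Ginv is None and (t.Z.getnnz(axis=1) <= 1).all()),
                      key=lambda i: -terms[i].Z.shape[1])
    absorb: list[int] = []
    for i in eligible:
        if all((terms[i].Z.T @ terms[j].Z).nnz == 0 for j in absorb):
            absorb.append(i)
    keep = [i for i in range(k) if i not in absorb]

    blocks = [X] + [terms[i].Z for i in keep] + [terms[i].Z for i in absorb]
    T = sparse.hstack(blocks, format="csr")
    TtT = (T.T @ T).tocsc()
    Tty = T.T @ y
    yty = float(y @ y)

    offs = np.cumsum([0, p] + [terms[i].Z.shape[1] for i in keep + absorb])
    sl = [None] * k     # per-term slice into the reordered equations
    for j, i in enumerate(keep + absorb):
        sl[i] = slice(offs[j + 1], offs[j + 2])
    q = np.array([t.Z.shape[1] for t in terms], dtype=float)

    n_core = offs[1 + len(keep)]
    core = slice(0, n_core)
    absc = slice(n_core, offs[-1])
    A_cc0 = TtT[core, core].tocsc()
    B = TtT[core, absc].tocsc()
    Bt = sparse.csr_matrix(B.T)
    d_zz = TtT[absc, absc].diagonal()   # diag(Z'Z) of absorbed terms

    vary = float(np.var(y, ddof=1))
    theta = (np.full(k + 1, vary / (k + 1)) if start is None
             else np.asarray(start, float).copy())
    if np.any(theta <= 0):
        raise ValueError("start values must be strictly positive")
    floor = 1e-8 * vary
    # a non-residual component this small relative to the phenotypic
    # variance is a REML boundary solution: freeze it so the active
    # components can converge by AI instead of stalling in EM
    boundary = 1e-3 * vary
    frozen = np.zeros(k + 1, dtype=bool)

    traj = []
    for it in range(1, max_iter + 1):
        se2 = theta[-1]
        lam = se2 / theta[:-1]

        # diagonal block of the absorbed equations
        d_lam = np.concatenate([np.full(terms[i].Z.shape[1], lam[i])
                                for i in absorb]) if absorb else np.empty(0)
        D = d_zz + d_lam

        # core LHS with structured penalties, minus the absorption term
        pen = [sparse.csr_matrix((p, p))]
        for i in keep:
            t = terms[i]
            pen.append(lam[i] * (t.Ginv if t.Ginv is not None
                                 else sparse.eye(t.Z.shape[1])))
        A_cc = (A_cc0 + sparse.block_diag(pen, format="csc")).toarray()
        if absorb:
            BD = B.multiply(1.0 / D)            # B D^-1, sparse
            S = A_cc - (BD @ Bt).toarray()
        else:
            BD = None
            S = A_cc
        try:
            c_low = cho_factor(S, lower=True)
        except np.linalg.LinAlgError:
            S[np.diag_indices_from(S)] += 1e-8 * np.abs(S).max()
            c_low = cho_factor(S, lower=True)
        logdetS = 2.0 * np.sum(np.log(np.diag(c_low[0])))
        Sinv, info = dpotri(c_low[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        Sinv = np.tril(Sinv) + np.tril(Sinv, -1).T  # upper triangle is scratch

        def msolve(v):
            """LHS^-1 @ v through the absorption block factorization."""
            vc_, va = v[:n_core], v[n_core:]
            xc = Sinv @ (vc_ - (BD @ va if absorb else 0.0))
            xa = (va - Bt @ xc) / D if absorb else np.empty(0)
            return np.concatenate([xc, xa])

        sol = msolve(Tty)
        ehat = y - T @ sol
        sse = float(ehat @ ehat)

        # selected entries of LHS^-1: kept blocks sit inside Sinv; the
        # absorbed diagonal is D^-1 + D^-1 B' Sinv B D^-1
        if absorb:
            R = Bt @ Sinv                        # n_abs x n_core, dense
            diag_abs = 1.0 / D + np.asarray(
                Bt.multiply(R).sum(axis=1)).ravel() / D ** 2
        uGu = np.empty(k)
        tr = np.empty(k)    # tr(G_i^-1 * Minv_ii)
        for i, t in enumerate(terms):
            ui = sol[sl[i]]
            if i in absorb:
                uGu[i] = float(ui @ ui)
                a0 = sl[i].start - n_core
                tr[i] = float(diag_abs[a0:a0 + t.Z.shape[1]].sum())
            elif t.Ginv is None:
                uGu[i] = float(ui @ ui)
                tr[i] = float(np.trace(Sinv[sl[i], sl[i]]))
            else:
                uGu[i] = float(ui @ (t.Ginv @ ui))
                tr[i] = float(t.Ginv.multiply(Sinv[sl[i], sl[i]]).sum())

        # REML log-likelihood (up to a constant): -0.5*(log|V| + log|X'V^-1X| + y'Py)
        # via the MME identities: log|V| = log|M| + n log se2 - sum_i q_i log lam_i
        #   ... tracked only for monotonicity diagnostics of EM rounds.
        logdetM = logdetS + float(np.sum(np.log(D))) if absorb else logdetS
        yPy = (yty - float(sol @ Tty)) / se2
        ll = -0.5 * (logdetM + (n - p) * np.log(se2)
                     - float(np.sum(q * np.log(lam))) + yPy)
        traj.append({"iter": it, "theta": theta.copy(), "loglik": ll})

        # gradient
        g = np.empty(k + 1)
        trPZGZ = (q - se2 * tr / theta[:-1]) / theta[:-1]
        g[:k] = -0.5 * (trPZGZ - uGu / theta[:-1] ** 2)
        trP = (n - p - float(np.sum(q - se2 * tr / theta[:-1]))) / se2
        g[k] = -0.5 * (trP - sse / se2 ** 2)

        # average information from working variates
        fs = [terms[i].Z @ (sol[sl[i]] / theta[i]) for i in range(k)]
        fs.append(ehat / se2)
        Fmat = np.column_stack(fs)
        TtF = np.asarray((T.T @ Fmat))
        MinvTtF = np.column_stack([msolve(TtF[:, j])
                                   for j in range(TtF.shape[1])])
        AI = 0.5 * (Fmat.T @ Fmat - TtF.T @ MinvTtF) / se2
        AI = 0.5 * (AI + AI.T)

        # proposed AI step over the active components, step-halved while
        # it leaves the parameter space; EM round as the last resort
        # (slow but monotone and positivity-preserving)
        act = ~frozen
        ai_ok = False
        new = theta.copy()
        try:
            delta = np.linalg.solve(AI[np.ix_(act, act)], g[act])
            if np.all(np.isfinite(delta)):
                s_len = 1.0
                for _ in range(8):
                    cand = theta[act] + s_len * delta
                    if np.all(cand > floor):
                        new[act] = cand
                        ai_ok = True
                        break
                    s_len *= 0.5
        except np.linalg.LinAlgError:
            pass
        if not ai_ok:
            em = np.empty_like(theta)
            em[:k] = (uGu + se2 * tr) / q
            em[k] = (yty - float(sol @ Tty)) / (n - p)
            new[act] = np.maximum(em, floor)[act]
            step = "EM"
        else:
            step = "AI"

        hit = (~frozen[:k]) & (new[:k] < boundary)
        if hit.any():
            for i in np.flatnonzero(hit):
                logger.warning(
                    "component %r collapsed to the zero boundary "
                    "(%.3g); frozen there", terms[i].name, new[i])
            frozen[:k] |= hit
            new[:k][hit] = np.maximum(new[:k][hit], floor)

        traj[-1]["step"] = step
        act = ~frozen
        rel = np.max(np.abs(new[act] - theta[act])
                     / np.maximum(np.abs(theta[act]), floor))
        theta = new
        if verbose:
            logger.info("REML iter %d (%s): theta=%s rel=%.2e", it, step,
                        np.round(theta, 4), rel)
        if rel < tol:
            se = np.full(k + 1, np.nan)
            se[act] = _ai_standard_errors(AI[np.ix_(act, act)])
            return {"theta": theta, "se": se, "iterations": it,
                    "trajectory": traj, "converged": True, "AI": AI,
                    "boundary": frozen.copy()}

    raise REMLError(f"AI-REML did not converge in {max_iter} iterations",
                    trajectory=traj)


def _ai_standard_errors(AI: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(AI)
        d = np.diag(cov)
        if np.any(d < 0):
            raise np.linalg.LinAlgError
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        logger.warning("AI matrix not PD at convergence; SEs via pseudo-inverse")
        return np.sqrt(np.abs(np.diag(np.linalg.pinv(AI))))


# ---------------------------------------------------------------------------
# Four-component repeatability model wrapper
# ---------------------------------------------------------------------------


def reml_estimate(design: DesignMatrices, rel_inv: sparse.spmatrix,
                  y: np.ndarray, start: VarianceComponents | None = None,
                  tol: float = 1e-8, max_iter: int = 200,
                  source: str = "AIREML") -> VarianceComponents:
    """AI-REML for the full repeatability animal model.

    ``rel_inv`` is A^-1 (source "AIREML") or H^-1 (source "ssGAIREML").
    Default starts split the phenotypic variance equally over the four
    components.
    """
    terms = [
        ("herd_year", design.Q, None),
        ("additive", design.Z, sparse.csr_matrix(rel_inv)),
        ("perm_env", design.W, None),
    ]
    s = None
    if start is not None:
        s = np.array([start.herd_year, start.additive, start.perm_env,
                      start.residual])
    res = reml_core(y, design.X, terms, start=s, tol=tol, max_iter=max_iter)
    th = res["theta"]
    se = res["se"]
    return VarianceComponents(
        herd_year=float(th[0]), additive=float(th[1]), perm_env=float(th[2]),
        residual=float(th[3]),
        se={n: float(v) for n, v in zip(COMPONENT_NAMES, se)},
        source=source, n_iterations=res["iterations"],
        converged=res["converged"],
    )


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------


def compare_methods(pedigree_vc: VarianceComponents,
                    singlestep_vc: VarianceComponents,
                    solutions_A=None, solutions_H=None,
                    pheno=None, ped=None) -> "pd.DataFrame":
    """Side-by-side components, h2 and accuracy gain of single-step.

    % increase in accuracy = 100 * (acc_ss - acc_ped) / acc_ped, computed
    per dataset (all/bulls/dams) when solutions with accuracies are given.
    """
    import pandas as pd

    from .model import infer_roles

    rows = []
    for name in COMPONENT_NAMES:
        rows.append({"quantity": name,
                     "AIREML": getattr(pedigree_vc, name),
                     "ssGAIREML": getattr(singlestep_vc, name)})
    rows.append({"quantity": "h2", "AIREML": pedigree_vc.h2,
                 "ssGAIREML": singlestep_vc.h2})

    if solutions_A is not None and solutions_H is not None:
        if not solutions_A.ebv.index.equals(solutions_H.ebv.index):
            raise ValueError("solution sets cover different animals")
        if solutions_A.accuracy is not None and solutions_H.accuracy is not None:
            subsets = {"all": solutions_A.accuracy.index}
            if ped is not None:
                roles = infer_roles(ped)
                idx = solutions_A.accuracy.index
                subsets["bulls"] = idx[roles.reindex(idx) == "bull"]
                subsets["dams"] = idx[roles.reindex(idx) == "dam"]
            for name, ids in subsets.items():
                if len(ids) == 0:
                    continue
                a = float(solutions_A.accuracy.loc[ids].mean())
                h = float(solutions_H.accuracy.loc[ids].mean())
                rows.append({"quantity": f"accuracy_{name}", "AIREML": a,
                             "ssGAIREML": h,
                             "pct_increase": 100.0 * (h - a) / a if a > 0 else np.nan})
    return pd.DataFrame(rows)
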