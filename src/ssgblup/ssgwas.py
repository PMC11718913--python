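"""Single-step GWAS: SNP effects back-solved from GEBVs.

Given GEBVs of genotyped animals from a single-step evaluation, marker
effects are recovered through the linear transform

    a_hat = D M' [M D M']^-1 u_hat = (1 / 2 sum p_j q_j) D M' G_D^-1 u_hat

with M the 2p-centred marker matrix, D the diagonal of marker weights
and G_D = M D M' / (2 sum p_j q_j) the weighted marker relationship.
Optional iterative reweighting (d_j proportional to a_j^2 2 p_j q_j,
renormalized to conserve total marker variance) sharpens large effects.
Downstream: percentage of additive genetic variance per sliding window
of adjacent SNPs, per-SNP normal-test p-values from the transformed
prediction-error covariance, and gene annotation with signed distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix

logger = logging.getLogger(__name__)

#: genome-wide significance threshold on the -log10 p scale
GENOME_WIDE_P = 5e-8
SIGNIFICANCE_LOG10P = -np.log10(GENOME_WIDE_P)  # = 7.30

#: windows contributing at least this percentage of additive variance
#: are flagged as candidate regions
MIN_WINDOW_PCT = 0.25

#: candidate genes are reported up to this distance from a SNP (bp)
NEAR_GENE_BP = 37_000


@dataclass
class SnpEffectResult:
    """Back-solved marker effects and derived association statistics."""

    effects: pd.DataFrame     # marker, chrom, pos, effect, weight, [se, log10p]
    windows: pd.DataFrame | None = None
    n_iterations: int = 1
    scale: float = 1.0        # k = 1/(2 sum p q)

    @property
    def significant(self) -> pd.DataFrame:
        if "log10p" not in self.effects:
            raise ValueError("p-values not computed")
        return self.effects[self.effects["log10p"] > SIGNIFICANCE_LOG10P]


def backsolve_snp_effects(M_centered: np.ndarray, G_used: np.ndarray,
                          u_hat_genotyped: np.ndarray,
                          weights: np.ndarray | None = None,
                          scale: float = 1.0) -> np.ndarray:
    """a_hat = scale * D M' G_used^-1 u_hat.

    ``G_used`` must be the unblended weighted marker relationship
    consistent with M, D and ``scale`` (so that M a_hat reconstructs
    u_hat exactly when u_hat lies in the marker column space). A singular
    G_used raises; add a small ridge to G_used (not a blend with A22,
    which belongs only in the evaluation step) if that happens.
    """
    M = np.asarray(M_centered, float)
    u = np.asarray(u_hat_genotyped, float)
    d = np.ones(M.shape[1]) if weights is None else np.asarray(weights, float)
    if np.any(d <= 0):
        raise ValueError("marker weights must be positive")
    try:
        Ginv_u = np.linalg.solve(G_used, u)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "G_used is singular; back-solving needs the unblended marker "
            "relationship — add a ridge epsilon rather than blending with A22"
        ) from None
    return scale * d * (M.T @ Ginv_u)


def marker_relationship(M_centered: np.ndarray, weights: np.ndarray | None,
                        freqs: np.ndarray) -> tuple[np.ndarray, float]:
    """Weighted marker relationship G_D = M D M' k and its scale k."""
    p = np.asarray(freqs, float)
    k = 1.0 / (2.0 * np.sum(p * (1.0 - p)))
    d = np.ones(M_centered.shape[1]) if weights is None else weights
    G = (M_centered * d) @ M_centered.T * k
    return G, k


def wang_weights(effects: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Reweighting d_j proportional to a_j^2 2 p_j q_j, renormalized so the
    total marker variance sum_j d_j 2 p_j q_j is conserved (equal-weight
    total). All-zero effects reset to equal weights with a warning."""
    p = np.asarray(freqs, float)
    tpq = 2.0 * p * (1.0 - p)
    raw = np.asarray(effects, float) ** 2 * tpq
    if not np.any(raw > 0):
        logger.warning("all SNP effects zero; weights reset to 1")
        return np.ones_like(raw)
    raw = np.maximum(raw, 1e-12 * raw.max())   # keep weights strictly positive
    return raw * tpq.sum() / float(raw @ tpq)


def iterate_weights(geno: GenotypeMatrix, u_hat_genotyped: np.ndarray,
                    n_iter: int = 1, ridge: float = 0.0
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Run the back-solve/reweight loop; n_iter=1 is the classic
    equal-weight pass. Returns (weights, effects, scale)."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    p = geno.allele_frequencies()
    M = geno.centered(p)
    d = np.ones(geno.n_markers)
    effects = np.zeros(geno.n_markers)
    k = 1.0
    for _ in range(n_iter):
        G, k = marker_relationship(M, d, p)
        if ridge > 0:
            G = G + ridge * np.eye(G.shape[0])
        effects = backsolve_snp_effects(M, G, u_hat_genotyped, d, scale=k)
        d_next = wang_weights(effects, p)
        d, d_prev = d_next, d
    return d_prev, effects, k


def window_variance(effects: np.ndarray, M_centered: np.ndarray,
                    marker_map: pd.DataFrame, window: int = 5,
                    min_pct: float = MIN_WINDOW_PCT) -> pd.DataFrame:
    """Percent of additive genetic variance per sliding SNP window.

    For each within-chromosome window w of ``window`` adjacent SNPs
    (step 1), var_w = Var(M_w a_w) across genotyped animals, expressed
    as a percentage of Var(M a) over all markers. Windows never span
    chromosome boundaries; chromosomes with fewer SNPs than the window
    are skipped with a log note.
    """
    a = np.asarray(effects, float)
    M = np.asarray(M_centered, float)
    total = float(np.var(M @ a))
    if total <= 0:
        raise ValueError("total additive variance from markers is zero")
    rows = []
    order = np.arange(len(a))
    chrom = marker_map["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = order[chrom == c]
        if len(idx) < window:
            logger.info("chromosome %s has %d < %d SNPs; windows skipped",
                        c, len(idx), window)
            continue
        score = M[:, idx] * a[idx]
        csum = np.cumsum(score, axis=1)
        for s in range(len(idx) - window + 1):
            w_score = csum[:, s + window - 1] - (csum[:, s - 1] if s > 0 else 0.0)
            pct = 100.0 * float(np.var(w_score)) / total
            rows.append({"chrom": c, "start_idx": int(idx[s]),
                         "start_pos": int(marker_map["pos"].iloc[idx[s]]),
                         "end_pos": int(marker_map["pos"].iloc[idx[s + window - 1]]),
                         "n_snps": window, "pct_variance": pct,
                         "flagged": pct >= min_pct})
    return pd.DataFrame(rows)


def snp_effect_variances(M_centered: np.ndarray, G_used: np.ndarray,
                         pev_cov: np.ndarray,
                         weights: np.ndarray | None = None,
                         scale: float = 1.0) -> np.ndarray:
    """Sampling variance of each back-solved effect.

    Propagates the prediction-error covariance of the genotyped GEBVs
    through the back-solve transform T = scale * D M' G^-1 and returns
    diag(T C T') (a diagonal approximation across markers).
    """
    M = np.asarray(M_centered, float)
    d = np.ones(M.shape[1]) if weights is None else np.asarray(weights, float)
    B = np.linalg.solve(G_used, M).T * (scale * d[:, None])   # T, m x n
    return np.einsum("ij,jk,ik->i", B, pev_cov, B)


def snp_pvalues(effects: np.ndarray, effect_sampling_variances: np.ndarray
                ) -> np.ndarray:
    """-log10 p per SNP from the two-sided normal test a_j / sd(a_j).

    Markers with zero sampling variance get NaN and a warning.
    """
    from scipy import stats

    a = np.asarray(effects, float)
    v = np.asarray(effect_sampling_variances, float)
    out = np.full(a.shape, np.nan)
    bad = v <= 0
    if bad.any():
        logger.warning("%d markers have zero sampling variance; p undefined",
                       int(bad.sum()))
    z = np.abs(a[~bad]) / np.sqrt(v[~bad])
    # log-scale survival function keeps extreme p-values exact
    out[~bad] = -(stats.norm.logsf(z) + np.log(2.0)) / np.log(10.0)
    return out


def run_gwas(geno: GenotypeMatrix, u_hat_genotyped: np.ndarray,
             pev_cov: np.ndarray | None = None, n_iter: int = 1,
             window: int = 5, min_pct: float = MIN_WINDOW_PCT,
             ridge: float = 0.0) -> SnpEffectResult:
    """Back-solve, reweight, window scan and (optionally) p-values."""
    weights, effects, k = iterate_weights(geno, u_hat_genotyped,
                                          n_iter=n_iter, ridge=ridge)
    p = geno.allele_frequencies()
    M = geno.centered(p)
    table = pd.DataFrame({
        "marker": geno.marker_ids,
        "chrom": geno.marker_map["chrom"].to_numpy(),
        "pos": geno.marker_map["pos"].to_numpy(),
        "effect": effects,
        "weight": weights,
    })
    if pev_cov is not None:
        G, k2 = marker_relationship(M, weights, p)
        if ridge > 0:
            G = G + ridge * np.eye(G.shape[0])
        v = snp_effect_variances(M, G, pev_cov, weights, scale=k2)
        table["se"] = np.sqrt(np.maximum(v, 0.0))
        table["log10p"] = snp_pvalues(effects, v)
    windows = window_variance(effects, M, geno.marker_map, window=window,
                              min_pct=min_pct)
    return SnpEffectResult(effects=table, windows=windows,
                           n_iterations=n_iter, scale=k)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


def read_bed_genes(path) -> pd.DataFrame:
    """Read a BED file of gene intervals into 1-based inclusive coords."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene"]
    df["start"] = df["start"].astype(np.int64) + 1   # BED is 0-based half-open
    df["end"] = df["end"].astype(np.int64)
    return df


def annotate_genes(significant_snps: pd.DataFrame, gene_table: pd.DataFrame,
                   near_bp: int = NEAR_GENE_BP, include_beyond: bool = True,
                   max_bp: int = 500_000) -> pd.DataFrame:
    """Genes on or near each SNP, with signed distances.

    A SNP inside a gene interval (1-based inclusive) is "on target"
    (distance 0); otherwise the distance is positive when the SNP lies
    right of the gene end and negative when left of the gene start.
    Genes within ``near_bp`` (inclusive) are classified ``within_37kb``;
    farther genes up to ``max_bp`` are kept with a ``beyond_37kb`` flag
    when ``include_beyond``.
    """
    g = gene_table
    if (g["start"] > g["end"]).any():
        raise ValueError("malformed gene interval with start > end")
    rows = []
    for _, snp in significant_snps.iterrows():
        sub = g[g["chrom"] == snp["chrom"]]
        pos = int(snp["pos"])
        dist = np.where(pos < sub["start"], pos - sub["start"],
                        np.where(pos > sub["end"], pos - sub["end"], 0))
        for (_, gene), d in zip(sub.iterrows(), dist):
            d = int(d)
            if d == 0:
                cls = "on_target"
            elif abs(d) <= near_bp:
                cls = "within_37kb"
            elif include_beyond and abs(d) <= max_bp:
                cls = "beyond_37kb"
            else:
                continue
            rows.append({
                "marker": snp.get("marker", ""), "chrom": snp["chrom"],
                "pos": pos, "gene": gene["gene"],
                "gene_size": int(gene["end"] - gene["start"] + 1),
                "distance": d, "classification": cls,
            })
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "gene",
                                       "gene_size", "distance",
                                       "classification"])
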