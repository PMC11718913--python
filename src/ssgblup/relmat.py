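"""Relationship matrices for pedigree and single-step genomic evaluation.

Builds the numerator relationship matrix A and its sparse inverse from a
pedigree (Henderson's rules with inbreeding), the genomic relationship
matrix G from SNP allele counts (VanRaden method 1), the pedigree
relationship among genotyped animals A22, and the single-step inverse

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

where G* is G blended with A22 for positive definiteness and scale
compatibility.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

UNKNOWN = 0  # external code for an unknown parent


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycles, missing parents, bad ids)."""


# ---------------------------------------------------------------------------
# Pedigree container
# ---------------------------------------------------------------------------


class PedigreeTable:
    """Animal/sire/dam triples, topologically ordered (parents first).

    Parameters
    ----------
    animal, sire, dam
        Equal-length sequences of ids. ``0`` (or ``None``/NaN) marks an
        unknown parent. Rows are re-ordered internally so every parent
        precedes its offspring; a cycle raises :class:`PedigreeError`.
    generation, sex, breed_group
        Optional per-animal annotations carried along by the simulator
        (sex is ``"M"``/``"F"``; generation 0 = founder).
    """

    def __init__(self, animal, sire, dam, generation=None, sex=None,
                 breed_group=None):
        animal = list(animal)
        n = len(animal)
        if len(set(animal)) != n:
            raise PedigreeError("duplicate animal ids in pedigree")
        if UNKNOWN in set(animal):
            raise PedigreeError("animal id 0 is reserved for unknown parents")
        sire = [UNKNOWN if _is_unknown(s) else s for s in sire]
        dam = [UNKNOWN if _is_unknown(d) else d for d in dam]
        known = set(animal)
        for p in list(sire) + list(dam):
            if p != UNKNOWN and p not in known:
                raise PedigreeError(f"parent {p!r} has no pedigree row")

        order = _toposort(animal, sire, dam)
        self.ids = np.asarray([animal[i] for i in order], dtype=object)
        pos = {a: i for i, a in enumerate(self.ids)}
        self.sire = np.asarray(
            [pos.get(sire[i], -1) if sire[i] != UNKNOWN else -1 for i in order],
            dtype=np.int64)
        self.dam = np.asarray(
            [pos.get(dam[i], -1) if dam[i] != UNKNOWN else -1 for i in order],
            dtype=np.int64)

        def _reorder(x):
            return None if x is None else np.asarray(list(x), dtype=object)[order]

        self.generation = _reorder(generation)
        self.sex = _reorder(sex)
        self.breed_group = _reorder(breed_group)
        self._F: np.ndarray | None = None

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.asarray([pos[a] for a in ids], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"id {e.args[0]!r} not in pedigree") from None

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-animal inbreeding coefficient F (founders: 0)."""
        if self._F is None:
            self._F = _inbreeding_meuwissen_luo(self.sire, self.dam)
        return self._F

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "PedigreeTable":
        """Build from a 3-column (animal, sire, dam) data frame."""
        a, s, d = (df.iloc[:, i] for i in range(3))
        return cls(a.tolist(), s.tolist(), d.tolist(), **kw)

    def to_frame(self) -> pd.DataFrame:
        sid = [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire]
        did = [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam]
        return pd.DataFrame({"animal": self.ids, "sire": sid, "dam": did})


def _is_unknown(p) -> bool:
    if p is None or p == UNKNOWN:
        return True
    try:
        return bool(np.isnan(p))
    except TypeError:
        return False


def _toposort(animal, sire, dam) -> list[int]:
    """Stable Kahn's algorithm over parent->offspring edges: input order is
    preserved whenever it is already consistent. Cycle -> error."""
    n = len(animal)
    pos = {a: i for i, a in enumerate(animal)}
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                children[pos[p]].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    heapq.heapify(queue)
    out: list[int] = []
    while queue:
        i = heapq.heappop(queue)
        out.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(queue, c)
    if len(out) != n:
        raise PedigreeError("pedigree contains a cycle (animal its own ancestor)")
    return out


def _inbreeding_meuwissen_luo(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients via the Meuwissen & Luo traversal.

    Uses A = T D T' with the gene-flow matrix T: the row of T for animal i
    is accumulated by walking ancestors in decreasing index order, so each
    ancestor's coefficient is final when popped. a_ii = sum T_ij^2 D_j and
    F_i = a_ii - 1. The Mendelian sampling variance D uses F = -1 for the
    phantom unknown parent, giving D = 1 (no parents) and 0.75 - F_s/4
    (one parent) as special cases of 0.5 - (F_s + F_d)/4.
    """
    n = len(sire)
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s < 0 or d < 0:
            continue  # F stays 0 with an unknown parent
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            w = coeff.pop(j, 0.0)
            if w == 0.0:
                continue
            a_ii += w * w * D[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        coeff[p] = 0.0
                        heapq.heappush(heap, -p)
                    coeff[p] += 0.5 * w
        F[i] = a_ii - 1.0
    return F


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Per-animal inbreeding coefficients (alias of ``ped.inbreeding``)."""
    return ped.inbreeding


# ---------------------------------------------------------------------------
# Pedigree relationship matrices
# ---------------------------------------------------------------------------


def build_A(ped: PedigreeTable) -> np.ndarray:
    """Numerator relationship matrix by the tabular method (dense).

    a_i,j = (a_s(i),j + a_d(i),j)/2 for j < i and
    a_i,i = 1 + a_s(i),d(i)/2; unknown parents contribute 0.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def build_A_inverse(ped: PedigreeTable) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules accounting for inbreeding.

    For each animal the contribution alpha_i (1, -1/2, -1/2) outer-product
    over (animal, sire, dam) is added, with alpha_i the inverse Mendelian
    sampling variance 1/(0.5 - (F_s + F_d)/4) (unknown parents use F = -1).
    """
    n = len(ped)
    F = ped.inbreeding
    s, d = ped.sire, ped.dam
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        Fs = F[s[i]] if s[i] >= 0 else -1.0
        Fd = F[d[i]] if d[i] >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (Fs + Fd))
        add(i, i, alpha)
        for p in (s[i], d[i]):
            if p >= 0:
                add(i, p, -alpha / 2)
                add(p, i, -alpha / 2)
        for p in (s[i], d[i]):
            for q in (s[i], d[i]):
                if p >= 0 and q >= 0:
                    add(p, q, alpha / 4)
    return sparse.csr_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)))


def build_A22(ped: PedigreeTable, genotyped_ids) -> np.ndarray:
    """Pedigree relationships among the genotyped subset (slice of A)."""
    idx = ped.index_of(genotyped_ids)
    return build_A(ped)[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Genotypes, QC and genomic relationships
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Allele-count genotypes (animals x markers) plus a marker map.

    ``codes`` holds 0/1/2 counts of the alternate allele as floats with
    NaN for missing calls. ``marker_map`` has columns (marker, chrom, pos)
    with 1-based positions strictly increasing within a chromosome.
    """

    ids: np.ndarray
    marker_ids: np.ndarray
    codes: np.ndarray
    marker_map: pd.DataFrame
    # ground-truth allele counts for the whole pedigree; populated by the
    # simulator so QTL effects can act on ungenotyped animals too
    pedigree_codes: np.ndarray | None = field(default=None, repr=False)
    pedigree_ids: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.ids), len(self.marker_ids)):
            raise ValueError("codes shape does not match ids x markers")
        with np.errstate(invalid="ignore"):
            valid = np.isnan(self.codes) | ((self.codes >= 0) & (self.codes <= 2))
        if not valid.all():
            # fractional values in [0, 2] are allowed for imputed calls
            raise ValueError("genotype codes must lie in [0, 2] or be missing")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("positions must strictly increase within a chromosome")

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per marker (missing ignored)."""
        return np.nanmean(self.codes, axis=0) / 2.0

    def marker_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.codes).mean(axis=1)

    def centered(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Mean-imputed, 2p-centred marker matrix W (animals x markers)."""
        p = self.allele_frequencies() if freqs is None else freqs
        W = self.codes - 2.0 * p
        return np.where(np.isnan(W), 0.0, W)


@dataclass
class QCReport:
    n_markers_before: int
    n_markers_after: int
    n_dropped_callrate: int
    n_dropped_maf: int
    n_animals_before: int
    n_animals_after: int
    n_missing_imputed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def qc_genotypes(geno: GenotypeMatrix, marker_callrate: float = 0.90,
                 maf: float = 0.05, animal_callrate: float = 0.90,
                 ) -> tuple[GenotypeMatrix, QCReport]:
    """Marker/animal quality control and mean imputation.

    Drops markers with call rate below ``marker_callrate`` or minor allele
    frequency not strictly above ``maf``, then animals with call rate below
    ``animal_callrate``; remaining missing codes are imputed to the marker
    mean 2p (so the centred code is 0).
    """
    cr = geno.marker_call_rate()
    p = geno.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf_obs = np.minimum(p, 1.0 - p)
    keep_cr = cr >= marker_callrate
    keep_maf = np.nan_to_num(maf_obs) > maf
    keep_m = keep_cr & keep_maf
    if not keep_m.any():
        raise ValueError("all markers removed by QC")
    codes = geno.codes[:, keep_m]
    a_cr = 1.0 - np.isnan(codes).mean(axis=1)
    keep_a = a_cr >= animal_callrate
    codes = codes[keep_a]

    n_missing = int(np.isnan(codes).sum())
    p_kept = np.nanmean(codes, axis=0) / 2.0
    codes = np.where(np.isnan(codes), 2.0 * p_kept, codes)

    out = GenotypeMatrix(
        ids=geno.ids[keep_a],
        marker_ids=geno.marker_ids[keep_m],
        codes=codes,
        marker_map=geno.marker_map.loc[np.asarray(keep_m)].reset_index(drop=True),
        pedigree_codes=geno.pedigree_codes[:, keep_m]
        if geno.pedigree_codes is not None else None,
        pedigree_ids=geno.pedigree_ids,
    )
    report = QCReport(
        n_markers_before=geno.n_markers,
        n_markers_after=int(keep_m.sum()),
        n_dropped_callrate=int((~keep_cr).sum()),
        n_dropped_maf=int((keep_cr & ~keep_maf).sum()),
        n_animals_before=geno.n_animals,
        n_animals_after=int(keep_a.sum()),
        n_missing_imputed=n_missing,
    )
    logger.info("QC: markers %d -> %d, animals %d -> %d, %d calls imputed",
                report.n_markers_before, report.n_markers_after,
                report.n_animals_before, report.n_animals_after, n_missing)
    return out, report


def build_G(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = W W' / (2 sum_j p_j (1 - p_j)) with W the 2p-centred allele counts
    and p the observed frequencies (unless supplied).
    """
    p = geno.allele_frequencies() if freqs is None else np.asarray(freqs, float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: G denominator is zero")
    W = geno.centered(p)
    return (W @ W.T) / denom


def blend_and_tune_G(G_raw: np.ndarray, A22: np.ndarray,
                     blend_beta: float = 0.05, tune: bool = True) -> np.ndarray:
    """Rescale G to the A22 scale and blend for positive definiteness.

    Tuning solves a + b*G for a, b so that the mean diagonal and mean
    off-diagonal of G match those of A22; blending returns
    (1 - beta) * G_tuned + beta * A22. Raises if the result is not PD.
    """
    G = np.asarray(G_raw, float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 must have identical shape/ordering")
    if tune and G.shape[0] > 1:
        dG, dA = np.mean(np.diag(G)), np.mean(np.diag(A22))
        n = G.shape[0]
        off = ~np.eye(n, dtype=bool)
        oG, oA = G[off].mean(), A22[off].mean()
        if not np.isclose(dG, oG):
            b = (dA - oA) / (dG - oG)
            a = oA - b * oG
            G = a + b * G
    G_star = (1.0 - blend_beta) * G + blend_beta * A22
    G_star = 0.5 * (G_star + G_star.T)
    try:
        np.linalg.cholesky(G_star)
    except np.linalg.LinAlgError:
        raise ValueError(
            "blended G is not positive definite; increase blend_beta") from None
    return G_star


def build_H_inverse(A_inv: sparse.spmatrix, A22_inv: np.ndarray,
                    G_star: np.ndarray, genotyped_idx) -> sparse.csr_matrix:
    """Single-step H^-1: A^-1 plus the genotyped-block correction.

    Adds G*^-1 - A22^-1 into the rows/columns of ``genotyped_idx`` (the
    positions of the genotyped animals within the pedigree ordering).
    Degenerates to A^-1 for an empty genotyped set or when G* = A22.
    """
    idx = np.asarray(genotyped_idx, dtype=np.int64)
    H_inv = sparse.csr_matrix(A_inv, copy=True)
    if idx.size == 0:
        return H_inv
    corr = np.linalg.inv(G_star) - A22_inv
    corr = 0.5 * (corr + corr.T)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    block = sparse.coo_matrix((corr.ravel(), (ii.ravel(), jj.ravel())),
                              shape=A_inv.shape)
    return sparse.csr_matrix(H_inv + block)


# ---------------------------------------------------------------------------
# One-stop construction
# ---------------------------------------------------------------------------


@dataclass
class RelationshipSet:
    """All matrices needed for one single-step evaluation."""

    A_inv: sparse.csr_matrix
    H_inv: sparse.csr_matrix | None
    A22: np.ndarray | None
    A22_inv: np.ndarray | None
    G_raw: np.ndarray | None
    G_star: np.ndarray | None
    genotyped_ids: np.ndarray | None
    genotyped_idx: np.ndarray | None

    def h_diagonal(self, ped: PedigreeTable) -> np.ndarray:
        """Diagonal of the single-step H: 1 + F with genotyped entries
        replaced by diag(G*). Used as the accuracy denominator scale."""
        d = 1.0 + ped.inbreeding
        if self.G_star is not None and self.genotyped_idx is not None:
            d = d.copy()
            d[self.genotyped_idx] = np.diag(self.G_star)
        return d


def relationship_set(ped: PedigreeTable, geno: GenotypeMatrix | None = None,
                     blend_beta: float = 0.05, tune: bool = True,
                     ) -> RelationshipSet:
    """Build A^-1 and, when genotypes are given, G*, A22^-1 and H^-1."""
    A_inv = build_A_inverse(ped)
    if geno is None or geno.n_animals == 0:
        return RelationshipSet(A_inv, sparse.csr_matrix(A_inv, copy=True),
                               None, None, None, None, None, None)
    missing = [a for a in geno.ids if a not in set(ped.ids)]
    if missing:
        raise PedigreeError(f"genotyped ids not in pedigree: {missing[:10]}")
    idx = ped.index_of(geno.ids)
    A22 = build_A22(ped, geno.ids)
    A22_inv = np.linalg.inv(A22)
    G_raw = build_G(geno)
    G_star = blend_and_tune_G(G_raw, A22, blend_beta=blend_beta, tune=tune)
    H_inv = build_H_inverse(A_inv, A22_inv, G_star, idx)
    return RelationshipSet(A_inv, H_inv, A22, A22_inv, G_raw, G_star,
                           geno.ids.copy(), idx)
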