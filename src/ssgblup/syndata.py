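"""Synthetic pedigree, genotype and phenotype generation.

Emulates the data structure of a tropical crossbred dairy population
recorded for days open (DO): a multi-generation pedigree under random
mating with a dairy-like sex ratio, a 50k-style SNP panel simulated by
gene dropping for a genotyped subset, and repeated records per cow from
the repeatability animal model

    y = Xb + Qh + Zu + Wp + e,

with b the fixed effects of breed group, parity and year-month of
calving, h ~ N(0, I sigma_h2) the herd-year effect, u ~ N(0, A sigma_u2)
the additive genetic effect, p ~ N(0, I sigma_p2) the permanent
environment effect, and e ~ N(0, I sigma_e2). Breeding values are drawn
by recursive Mendelian sampling so the cost stays linear in pedigree
size; ground truth is returned for recovery tests.

Default sizes are a 10-50x reduction of the study population (36k cows
with records, 79k pedigree animals, 882 genotyped on a 50k chip); the
default variance components, record bounds, breed-group effects and
phenotypic mean mirror the estimates reported for the Thai-Holstein DO
data (additive 18.23, herd-year 30.41, permanent environment 51.19,
residual 707.87 days^2; records edited to 35-150 days; mean ~97 days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix, PedigreeTable

logger = logging.getLogger(__name__)

#: Published days-open estimates used as the default truth, in days^2.
DEFAULT_VARIANCES = {"herd_year": 30.41, "additive": 18.23,
                     "perm_env": 51.19, "residual": 707.87}

#: Breed-group fixed effects in days (group 2 is the reference).
DEFAULT_BG_EFFECTS = (0.372, 0.0, -1.508)

#: Parity fixed effects in days: highest DO at second parity, lowest at
#: fifth — the qualitative pattern of the study population.
DEFAULT_PARITY_EFFECTS = (0.0, 2.5, 1.0, -0.5, -2.5)

#: Overall phenotypic baseline (days).
DEFAULT_MEAN = 97.02


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Knobs of the synthetic population; defaults are the study conditions
    at desk scale."""

    n_founders: int = 100
    n_generations: int = 2
    mating_scheme: str = "random"
    n_cows_with_records: int = 1500
    parities_per_cow: tuple[int, int] = (1, 5)
    n_breed_groups: int = 3
    n_herd_years: int = 50
    n_year_months: int = 24
    true_variances: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCES))
    record_bounds: tuple[float, float] | None = (35.0, 150.0)
    mean_days_open: float = DEFAULT_MEAN
    bg_effects: tuple[float, ...] = DEFAULT_BG_EFFECTS
    parity_effects: tuple[float, ...] = DEFAULT_PARITY_EFFECTS
    year_month_sd: float = 6.0
    male_fraction: float = 0.10
    n_snps: int = 2000
    n_chromosomes: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    genotyped_fraction: float = 0.2
    #: which animals the genotyped subset is drawn from: "nonfounders"
    #: spans parents and offspring like a real genotyping campaign
    #: (AI sires plus cows); "final" restricts to the last generation
    genotyped_scope: str = "nonfounders"
    qtl: list[tuple[int, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        for k, v in self.true_variances.items():
            if v < 0:
                raise ConfigError(f"variance {k} must be >= 0, got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.record_bounds is not None:
            mn, mx = self.record_bounds
            if not mn < mx:
                raise ConfigError("record_bounds must satisfy min < max")
        if not (0.0 < self.genotyped_fraction <= 1.0):
            raise ConfigError("genotyped_fraction must be in (0, 1]")
        plo, phi = self.parities_per_cow
        if not (1 <= plo <= phi <= 5):
            raise ConfigError("parities_per_cow must be within 1..5")
        if self.mating_scheme != "random":
            raise ConfigError(f"unknown mating scheme {self.mating_scheme!r}")
        if self.genotyped_scope not in ("nonfounders", "final", "all"):
            raise ConfigError(f"unknown genotyped_scope {self.genotyped_scope!r}")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founders to mate")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Ground truth behind one simulated data set."""

    animal_ids: np.ndarray
    true_breeding_values: np.ndarray        # per pedigree animal, days
    true_pe_effects: dict                   # cow id -> days
    true_herd_year_effects: np.ndarray      # per level, days
    true_fixed_effects: dict                # factor -> per-level effects
    qtl_effects: dict                       # marker index -> days/allele


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> PedigreeTable:
    """Generation-discrete pedigree under random mating.

    Founders (generation 0) have unknown parents. Each later generation
    draws a sire among the previous generation's males and a dam among
    its females. Few males per generation (``male_fraction``) mimic an
    AI-based dairy population; females of generations >= 1 are the
    candidate record cows.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_generations < 0:
        raise ConfigError("n_generations must be >= 0")
    n_f_per_gen = -(-config.n_cows_with_records // max(config.n_generations, 1))
    n_m_per_gen = max(2, int(round(n_f_per_gen * config.male_fraction /
                                   (1 - config.male_fraction))))

    ids: list[int] = []
    sire: list[int] = []
    dam: list[int] = []
    generation: list[int] = []
    sex: list[str] = []

    n_male_f = max(2, int(round(config.n_founders * config.male_fraction)))
    for i in range(config.n_founders):
        ids.append(i + 1)
        sire.append(0)
        dam.append(0)
        generation.append(0)
        sex.append("M" if i < n_male_f else "F")
    if n_male_f >= config.n_founders:
        raise ConfigError("founder set has no females; increase n_founders")

    next_id = config.n_founders + 1
    prev = list(range(config.n_founders))
    for g in range(1, config.n_generations + 1):
        males = [k for k in prev if sex[k] == "M"]
        females = [k for k in prev if sex[k] == "F"]
        if not males or not females:
            raise ConfigError("a generation lacks one sex; adjust sizes")
        cur: list[int] = []
        n_off = n_f_per_gen + n_m_per_gen
        for j in range(n_off):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            ids.append(next_id)
            sire.append(ids[s])
            dam.append(ids[d])
            generation.append(g)
            sex.append("M" if j < n_m_per_gen else "F")
            cur.append(next_id - 1)
            next_id += 1
        prev = cur

    bg = _assign_breed_groups(np.asarray(sire), np.asarray(dam),
                              np.asarray(ids), config, rng)
    return PedigreeTable(ids, sire, dam, generation=generation, sex=sex,
                         breed_group=bg)


def _assign_breed_groups(sire, dam, ids, config, rng) -> np.ndarray:
    """Founders draw a breed group uniformly; offspring inherit the dam's
    (the Holstein-fraction class travels mostly through the cow line)."""
    pos = {a: i for i, a in enumerate(ids)}
    bg = np.zeros(len(ids), dtype=np.int64)
    for i in range(len(ids)):
        if dam[i] == 0:
            bg[i] = rng.integers(1, config.n_breed_groups + 1)
        else:
            bg[i] = bg[pos[dam[i]]]
    return bg


# ---------------------------------------------------------------------------
# Genotypes by gene dropping
# ---------------------------------------------------------------------------


def simulate_genotypes(ped: PedigreeTable, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop a SNP panel through the pedigree.

    Founder alleles are Bernoulli(p_j) with p_j ~ U(maf_range) per marker;
    each non-founder inherits one allele per parent, markers transmitted
    independently (no linkage). ``genotyped_fraction`` of the animals in
    ``genotyped_scope`` (by default all non-founders, so the subset spans
    sires, dams and final-generation animals) is returned as genotyped;
    the full-pedigree allele counts are kept on the result for QTL
    ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    n, m = len(ped), config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        for k, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent < 0:
                hap[i, k] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[i, k] = hap[parent, pick, np.arange(m)]
    codes = hap.sum(axis=1).astype(np.int8)

    marker_map = _marker_map(config, rng)

    if ped.generation is not None and config.genotyped_scope != "all":
        gen = np.asarray([int(g) for g in ped.generation])
        if config.genotyped_scope == "final":
            mask = gen == gen.max()
        else:
            mask = gen > 0 if gen.max() > 0 else gen == 0
    else:
        mask = np.ones(n, dtype=bool)
    cand = np.flatnonzero(mask)
    k = max(1, int(round(config.genotyped_fraction * cand.size)))
    chosen = np.sort(rng.choice(cand, size=k, replace=False))

    return GenotypeMatrix(
        ids=ped.ids[chosen],
        marker_ids=marker_map["marker"].to_numpy(),
        codes=codes[chosen].astype(float),
        marker_map=marker_map,
        pedigree_codes=codes,
        pedigree_ids=ped.ids.copy(),
    )


def _marker_map(config: SimConfig, rng) -> pd.DataFrame:
    """Markers split evenly over chromosomes, 1-based bp positions
    strictly increasing within each chromosome."""
    m = config.n_snps
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1),
                       -(-m // config.n_chromosomes))[:m]
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chroms):
        k = int((chroms == c).sum())
        gaps = rng.integers(1_000, 100_000, size=k)
        pos[chroms == c] = np.cumsum(gaps)
    marker = np.array([f"snp{c}_{i}" for i, c in enumerate(chroms, 1)],
                      dtype=object)
    return pd.DataFrame({"marker": marker, "chrom": chroms, "pos": pos})


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _sample_breeding_values(ped: PedigreeTable, sigma_u2: float, rng
                            ) -> np.ndarray:
    """Recursive Mendelian sampling: u_i = (u_s + u_d)/2 + phi_i with
    Var(phi_i) = sigma_u2 * (0.5 - (F_s + F_d)/4), unknown-parent terms
    dropped and their share of variance kept (F = -1 convention). Gives
    Cov(u) = A sigma_u2 without forming A."""
    n = len(ped)
    F = ped.inbreeding
    u = np.zeros(n)
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        Fs = F[s] if s >= 0 else -1.0
        Fd = F[d] if d >= 0 else -1.0
        mean = 0.0
        if s >= 0:
            mean += 0.5 * u[s]
        if d >= 0:
            mean += 0.5 * u[d]
        v = sigma_u2 * (0.5 - 0.25 * (Fs + Fd))
        u[i] = mean + np.sqrt(v) * z[i]
    return u


def simulate_phenotypes(ped: PedigreeTable, geno: GenotypeMatrix | None,
                        config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Repeated days-open records for the record cows.

    Each record cow (non-founder female, up to ``n_cows_with_records``)
    receives 1-5 records, one per parity, with herd-year and year-month
    labels drawn per record. When ``record_bounds`` is set, records
    falling outside are dropped (edited away), not truncated in value.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    vc = config.true_variances
    for k in ("herd_year", "additive", "perm_env", "residual"):
        if vc[k] < 0:
            raise ConfigError(f"negative variance {k}")

    u = _sample_breeding_values(ped, vc["additive"], rng)

    qtl_effects: dict[int, float] = {}
    if config.qtl:
        if geno is None or geno.pedigree_codes is None:
            raise ConfigError("qtl effects require simulated genotypes")
        p_all = geno.pedigree_codes.mean(axis=0) / 2.0
        for j, a in config.qtl:
            u = u + a * (geno.pedigree_codes[:, j] - 2.0 * p_all[j])
            qtl_effects[int(j)] = float(a)

    hy = rng.normal(0.0, np.sqrt(vc["herd_year"]), size=config.n_herd_years)
    ym = rng.normal(0.0, config.year_month_sd, size=config.n_year_months)
    bg_eff = np.asarray(config.bg_effects, dtype=float)
    par_eff = np.asarray(config.parity_effects, dtype=float)

    if ped.sex is None or ped.generation is None:
        raise ConfigError("pedigree lacks sex/generation annotations")
    is_cow = np.asarray([s == "F" and int(g) > 0
                         for s, g in zip(ped.sex, ped.generation)])
    cow_idx = np.flatnonzero(is_cow)[:config.n_cows_with_records]
    if cow_idx.size == 0:
        raise ConfigError("no candidate record cows in pedigree")

    pe = rng.normal(0.0, np.sqrt(vc["perm_env"]), size=cow_idx.size)
    lo, hi = config.parities_per_cow
    n_rec = rng.integers(lo, hi + 1, size=cow_idx.size)

    rows = []
    for c, (i, npar) in enumerate(zip(cow_idx, n_rec)):
        bg = int(ped.breed_group[i]) if ped.breed_group is not None else 1
        for parity in range(1, int(npar) + 1):
            h = int(rng.integers(config.n_herd_years))
            t = int(rng.integers(config.n_year_months))
            y = (config.mean_days_open + bg_eff[bg - 1] + par_eff[parity - 1]
                 + ym[t] + hy[h] + u[i] + pe[c]
                 + rng.normal(0.0, np.sqrt(vc["residual"])))
            rows.append((ped.ids[i], parity, bg, f"hy{h + 1}", f"ym{t + 1}", y))

    pheno = pd.DataFrame(rows, columns=["cow_id", "parity", "breed_group",
                                        "herd_year", "year_month", "days_open"])
    if config.record_bounds is not None:
        mn, mx = config.record_bounds
        keep = (pheno["days_open"] >= mn) & (pheno["days_open"] <= mx)
        dropped = int((~keep).sum())
        if dropped > 0.5 * len(pheno):
            logger.warning("record bounds dropped %d of %d records (>50%%)",
                           dropped, len(pheno))
        pheno = pheno.loc[keep].reset_index(drop=True)

    truth = SimTruth(
        animal_ids=ped.ids.copy(),
        true_breeding_values=u,
        true_pe_effects={ped.ids[i]: pe[c] for c, i in enumerate(cow_idx)},
        true_herd_year_effects=hy,
        true_fixed_effects={"mean": config.mean_days_open,
                            "breed_group": bg_eff, "parity": par_eff,
                            "year_month": ym},
        qtl_effects=qtl_effects,
    )
    return pheno, truth


def simulate_dataset(config: SimConfig, genotypes: bool = True):
    """Convenience: pedigree, (optional) genotypes and phenotypes in one call."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config) if genotypes and config.n_snps > 0 else None
    pheno, truth = simulate_phenotypes(ped, geno, config)
    return ped, geno, pheno, truth
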