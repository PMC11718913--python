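import numpy as np
import pandas as pd
import pytest

from ssgblup.relmat import GenotypeMatrix, PedigreeTable
from ssgblup.syndata import SimConfig, simulate_dataset


@pytest.fixture
def trio():
    """Unrelated sire and dam with one offspring."""
    return PedigreeTable([1, 2, 3], [0, 0, 1], [0, 0, 2])


@pytest.fixture
def full_sib_pedigree():
    """Two founders, two full sibs, and their (inbred) offspring."""
    return PedigreeTable([1, 2, 3, 4, 5], [0, 0, 1, 1, 3], [0, 0, 2, 2, 4])


def random_pedigree(n: int, seed: int) -> PedigreeTable:
    """Random valid pedigree: each animal's parents drawn (or unknown)
    among earlier animals."""
    rng = np.random.default_rng(seed)
    sire, dam = [], []
    for i in range(n):
        if i < 2 or rng.random() < 0.2:
            sire.append(0)
            dam.append(0)
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sire.append(int(s) + 1)
            dam.append(int(d) + 1)
    return PedigreeTable(list(range(1, n + 1)), sire, dam)


@pytest.fixture
def small_dataset():
    """A compact simulated dataset with genotypes, shared across tests."""
    cfg = SimConfig(n_cows_with_records=120, n_founders=30, n_generations=2,
                    parities_per_cow=(1, 3), n_herd_years=15, n_year_months=8,
                    n_snps=300, n_chromosomes=3, genotyped_fraction=0.8,
                    record_bounds=None, seed=42)
    ped, geno, pheno, truth = simulate_dataset(cfg)
    return {"config": cfg, "ped": ped, "geno": geno, "pheno": pheno,
            "truth": truth}


def toy_genotypes(codes, chrom=None, pos=None) -> GenotypeMatrix:
    codes = np.asarray(codes, dtype=float)
    n, m = codes.shape
    chrom = np.ones(m, dtype=int) if chrom is None else np.asarray(chrom)
    pos = np.arange(1, m + 1) * 1000 if pos is None else np.asarray(pos)
    mm = pd.DataFrame({"marker": [f"m{j}" for j in range(m)],
                       "chrom": chrom, "pos": pos})
    return GenotypeMatrix(ids=np.arange(1, n + 1), marker_ids=mm["marker"].
                          to_numpy(), codes=codes, marker_map=mm)
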