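"""End-to-end orchestration: simulate -> qc -> varcomp -> evaluate -> gwas.

Also houses the run configuration (YAML round-trip), bit-stable tabular
I/O (TSV with fixed 6-significant-digit formatting) and the descriptive
phenotype summary. Identical configuration and seed give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from . import model, relmat, ssgwas, syndata, varcomp

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    pheno_path: str | None = None
    ped_path: str | None = None
    geno_prefix: str | None = None     # <prefix>.txt codes + <prefix>.map TSV
    genes_path: str | None = None      # BED gene table
    vc_path: str | None = None         # reuse components instead of REML
    mode: str = "single-step"          # or "pedigree"
    out_dir: str = "ssgblup_out"
    simulate: bool = False
    sim: dict = field(default_factory=dict)   # SimConfig overrides
    marker_callrate: float = 0.90
    maf: float = 0.05
    animal_callrate: float = 0.90
    blend_beta: float = 0.05
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    window: int = 5
    min_window_pct: float = ssgwas.MIN_WINDOW_PCT
    threshold_log10p: float = float(ssgwas.SIGNIFICANCE_LOG10P)
    near_gene_bp: int = ssgwas.NEAR_GENE_BP
    top_fraction: float = 0.20
    bg_reference: int = 2
    gwas_iterations: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("pedigree", "single-step"):
            raise ValueError(f"unknown mode {self.mode!r}")
        # YAML has no tuple type: normalize so configs round-trip unchanged
        self.sim = {k: list(v) if isinstance(v, tuple) else v
                    for k, v in self.sim.items()}
        for name, lo, hi in (("marker_callrate", 0, 1), ("maf", 0, 0.5),
                             ("animal_callrate", 0, 1), ("blend_beta", 0, 1),
                             ("top_fraction", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pedigree(ped: relmat.PedigreeTable, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> relmat.PedigreeTable:
    return relmat.PedigreeTable.from_frame(pd.read_csv(path))


def write_genotypes(geno: relmat.GenotypeMatrix, prefix) -> None:
    """0/1/2 text matrix (<prefix>.txt, NA for missing) + map TSV."""
    prefix = str(prefix)
    codes = pd.DataFrame(geno.codes, columns=geno.marker_ids)
    codes.insert(0, "animal", geno.ids)
    codes.to_csv(prefix + ".txt", sep="\t", index=False, na_rep="NA",
                 float_format="%g")
    write_tsv(geno.marker_map, prefix + ".map")


def read_genotypes(prefix) -> relmat.GenotypeMatrix:
    prefix = str(prefix)
    codes = pd.read_csv(prefix + ".txt", sep="\t")
    marker_map = pd.read_csv(prefix + ".map", sep="\t")
    ids = codes.pop("animal").to_numpy(object)
    return relmat.GenotypeMatrix(ids=ids,
                                 marker_ids=codes.columns.to_numpy(object),
                                 codes=codes.to_numpy(float),
                                 marker_map=marker_map)


def write_matrix(matrix, ids, path) -> None:
    """Write a (relationship) matrix as TSV with ids as header/index."""
    arr = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
    pd.DataFrame(arr, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT)


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), df.index.to_numpy()


def write_vc(vc: varcomp.VarianceComponents, path) -> None:
    Path(path).write_text(yaml.safe_dump(vc.to_dict(), sort_keys=False))


def read_vc(path) -> varcomp.VarianceComponents:
    d = yaml.safe_load(Path(path).read_text())
    return varcomp.VarianceComponents(
        herd_year=d["herd_year"], additive=d["additive"],
        perm_env=d["perm_env"], residual=d["residual"],
        se=d.get("se", {}), source=d.get("source", "AIREML"))


def write_solutions(sols: model.SolutionSet, path) -> None:
    frames = []
    for kind, series in (("fixed", sols.fixed), ("herd_year", sols.herd_year),
                         (sols.kind, sols.ebv), ("perm_env", sols.perm_env)):
        df = pd.DataFrame({"id": series.index.astype(str),
                           "effect": kind, "estimate": series.to_numpy()})
        if kind == sols.kind:
            df["pev"] = (sols.pev.to_numpy() if sols.pev is not None else np.nan)
            df["accuracy"] = (sols.accuracy.to_numpy()
                              if sols.accuracy is not None else np.nan)
        frames.append(df)
    write_tsv(pd.concat(frames, ignore_index=True), path)


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------


def summarize_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-breed-group and overall n / min / max / mean / SD of records.

    The overall mean is the record-count-weighted mean of the group
    means by construction.
    """
    if len(pheno) == 0:
        raise ValueError("empty phenotype table")

    def _stats(sub, label):
        y = sub["days_open"]
        return {"group": label, "n_records": len(y),
                "n_cows": sub["cow_id"].nunique(), "min": y.min(),
                "max": y.max(), "mean": y.mean(), "sd": y.std(ddof=1)}

    rows = [_stats(pheno, "overall")]
    for g, sub in pheno.groupby("breed_group"):
        rows.append(_stats(sub, f"BG{g}"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages; writes outputs and a MANIFEST into
    ``config.out_dir`` and returns the in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    results: dict = {}
    config.to_yaml(out / "config.yaml")

    def done(stage):
        manifest.append(stage)
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")

    try:
        # ---- inputs -----------------------------------------------------
        if config.simulate:
            sim_cfg = syndata.SimConfig(**{"seed": config.seed, **config.sim})
            ped, geno, pheno, truth = syndata.simulate_dataset(sim_cfg)
            write_pedigree(ped, out / "pedigree.csv")
            write_phenotypes(pheno, out / "phenotypes.csv")
            if geno is not None:
                write_genotypes(geno, out / "genotypes")
            _write_truth(truth, out)
            results["truth"] = truth
        else:
            if not (config.pheno_path and config.ped_path):
                raise ValueError("pheno_path and ped_path required unless simulating")
            ped = read_pedigree(config.ped_path)
            pheno = read_phenotypes(config.pheno_path)
            geno = (read_genotypes(config.geno_prefix)
                    if config.geno_prefix else None)
        results.update(ped=ped, pheno=pheno, geno=geno)
        write_tsv(summarize_phenotypes(pheno), out / "pheno_summary.tsv")
        done("inputs")

        # ---- QC and relationship matrices -------------------------------
        if config.mode == "pedigree" and geno is not None:
            logger.warning("mode=pedigree: supplied genotypes are ignored")
            geno = None
        if geno is not None:
            geno, qc_report = relmat.qc_genotypes(
                geno, config.marker_callrate, config.maf,
                config.animal_callrate)
            write_tsv(qc_report.to_frame(), out / "qc_report.tsv")
            results["qc_report"] = qc_report
        rels = relmat.relationship_set(ped, geno, blend_beta=config.blend_beta)
        rel_inv = rels.H_inv if config.mode == "single-step" else rels.A_inv
        results["relationships"] = rels
        done("relmat")

        # ---- variance components ----------------------------------------
        design = model.build_design(pheno, ped,
                                    references={"breed_group": config.bg_reference})
        y = pheno["days_open"].to_numpy(float)
        if config.vc_path:
            vc = read_vc(config.vc_path)
        else:
            source = "ssGAIREML" if config.mode == "single-step" else "AIREML"
            vc = varcomp.reml_estimate(design, rel_inv, y, tol=config.reml_tol,
                                       max_iter=config.reml_max_iter,
                                       source=source)
        write_vc(vc, out / "vc.yaml")
        results["vc"] = vc
        done("varcomp")

        # ---- evaluation --------------------------------------------------
        single = config.mode == "single-step"
        sols = model.evaluate(pheno, ped, rel_inv, vc, single_step=single,
                              references={"breed_group": config.bg_reference},
                              rel_diag=rels.h_diagonal(ped) if single else None)
        write_solutions(sols, out / "solutions.tsv")
        rankings = model.summarize_rankings(sols, pheno, ped,
                                            top_fraction=config.top_fraction)
        write_tsv(rankings, out / "rankings.tsv")
        results.update(solutions=sols, rankings=rankings)
        done("evaluate")

        # ---- GWAS --------------------------------------------------------
        if config.mode == "single-step" and geno is not None:
            idx = rels.genotyped_idx
            u_g = sols.ebv.to_numpy()[idx]
            pev_cov = _genotyped_pev_cov(design, rel_inv, vc, idx)
            gw = ssgwas.run_gwas(geno, u_g, pev_cov=pev_cov,
                                 n_iter=config.gwas_iterations,
                                 window=config.window,
                                 min_pct=config.min_window_pct)
            write_tsv(gw.effects, out / "snp_effects.tsv")
            write_tsv(gw.windows, out / "windows.tsv")
            if "log10p" in gw.effects:
                write_tsv(gw.effects[["chrom", "pos", "log10p", "effect"]],
                          out / "manhattan.tsv")
            sig = gw.effects[gw.effects["log10p"] > config.threshold_log10p]
            if config.genes_path:
                genes = ssgwas.read_bed_genes(config.genes_path)
                annot = ssgwas.annotate_genes(sig, genes,
                                              near_bp=config.near_gene_bp)
                sig = sig.merge(annot, on=["marker", "chrom", "pos"], how="left")
            write_tsv(sig, out / "significant_snps.tsv")
            results["gwas"] = gw
            done("gwas")

        _write_report(out, config, results)
        done("report")
    except Exception:
        (out / "MANIFEST").write_text("\n".join(manifest + ["FAILED"]) + "\n")
        raise
    return results


def _genotyped_pev_cov(design, rel_inv, vc, genotyped_idx) -> np.ndarray:
    """Prediction-error covariance of the genotyped animals' GEBVs from a
    dense factorization of the MME."""
    from scipy.linalg import cho_factor, cho_solve

    mme = model.assemble_mme(design, rel_inv, vc, single_step=True)
    dense = mme.LHS.toarray()
    c = cho_factor(dense, lower=True)
    sl = mme.slices["additive"]
    cols = np.asarray(genotyped_idx) + sl.start
    rhs = np.zeros((dense.shape[0], len(cols)))
    rhs[cols, np.arange(len(cols))] = 1.0
    inv_cols = cho_solve(c, rhs)
    return inv_cols[cols] * vc.residual


def _write_truth(truth: syndata.SimTruth, out: Path) -> None:
    write_tsv(pd.DataFrame({"animal": truth.animal_ids,
                            "true_bv": truth.true_breeding_values}),
              out / "truth_breeding_values.tsv")


def _write_report(out: Path, config: RunConfig, results: dict) -> None:
    lines = ["# ssgblup run report", "",
             f"mode: {config.mode}", f"seed: {config.seed}", ""]
    if "pheno" in results:
        lines += ["## Phenotype summary", "",
                  summarize_phenotypes(results["pheno"]).to_string(index=False), ""]
    if "vc" in results:
        vc = results["vc"]
        lines += ["## Variance components", ""]
        for name in varcomp.COMPONENT_NAMES:
            se = vc.se.get(name, float("nan"))
            lines.append(f"- {name}: {getattr(vc, name):.2f} ({se:.2f})")
        lines += [f"- h2: {vc.h2:.4f}", f"- repeatability: {repr_round(vc)}", ""]
    if "rankings" in results:
        lines += ["## Rankings", "",
                  results["rankings"].to_string(index=False), ""]
    if "gwas" in results:
        gw = results["gwas"]
        n_sig = int((gw.effects.get("log10p", pd.Series(dtype=float))
                     > config.threshold_log10p).sum())
        n_flag = int(gw.windows["flagged"].sum()) if gw.windows is not None else 0
        lines += ["## GWAS", "", f"- significant SNPs: {n_sig}",
                  f"- flagged windows (>= {config.min_window_pct}%): {n_flag}", ""]
    (out / "report.md").write_text("\n".join(lines))


def repr_round(vc) -> str:
    return f"{varcomp.repeatability(vc):.4f}"
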