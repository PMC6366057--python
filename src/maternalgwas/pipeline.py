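"""End-to-end orchestration: simulate -> qc -> stratification -> reml ->
drp -> gwas -> genes, with a machine-readable run manifest.

Every stage writes its intermediates as the module-native text formats
(PLINK triple, CSV/TSV), so stages are independently inspectable and a
run is fully reproducible from its config and seed. The manifest
records the config hash, the seed, and input/output counts per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blup_drp import deregress, filter_drp, solve_mme
from .gene_annotation import gene_test, map_snps_to_genes
from .gwas import ScanConfig, effect_correlations, run_scan
from .io_formats import write_genes, write_pedigree, write_phenotypes, \
    write_plink
from .kinship import build_G, kmeans_clusters, pca
from .qc import QCReport, drop_duplicate_animals, filter_bw0_range, \
    filter_studentized_outliers, ld_prune, snp_qc
from .reml import fit_greml, fit_maternal_model, precorrect_phenotypes
from .synthetic_data import SimConfig, genotyped_ids, simulate_gene_table, \
    simulate_phenotypes, simulate_population

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {},                      # SimConfig overrides
    "n_genes": 40,
    "corrections": ["none", "A", "G", "LOCO"],
    "dependents": ["phenotype", "dDRP", "mDRP"],
    "drp_c": 0.5,
    "alpha": 0.05,
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **user}
    cfg["simulate"] = {**DEFAULT_CONFIG["simulate"], **user.get("simulate", {})}
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the full stage DAG; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    sim_cfg = SimConfig(seed=cfg["seed"], **cfg.get("simulate", {}))
    geno_all, ped = simulate_population(sim_cfg)
    pheno, truth = simulate_phenotypes(geno_all, ped, sim_cfg)
    genes = simulate_gene_table(sim_cfg, n_genes=cfg["n_genes"])
    geno = geno_all.subset(individuals=genotyped_ids(ped))
    write_plink(geno, str(outdir / "genotypes"))
    write_pedigree(ped, outdir / "pedigree.csv")
    write_phenotypes(pheno, outdir / "phenotypes.csv")
    write_genes(genes, outdir / "genes.tsv")
    manifest["stages"]["simulate"] = {
        "n_animals_genotyped": geno.n_individuals,
        "n_snps": geno.n_snps,
        "n_pedigree": len(ped.records),
        "n_phenotypes": len(pheno.records),
        "n_genes": len(genes.records),
    }

    # --- qc -----------------------------------------------------------
    report = QCReport()
    pheno_qc = filter_bw0_range(pheno, report=report)
    for trait in ("BW23", "BW1314"):
        if (pheno_qc.records["trait"] == trait).any():
            pheno_qc = filter_studentized_outliers(pheno_qc, trait,
                                                   report=report)
    geno_qc, _ = snp_qc(geno, report=report)
    geno_qc, _ = drop_duplicate_animals(geno_qc, report=report)
    pruned = ld_prune(geno_qc)
    report.add("ld_prune", geno_qc.n_snps, geno_qc.n_snps - len(pruned),
               r2_max=0.25)
    report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = {
        "n_phenotypes": len(pheno_qc.records),
        "n_snps": geno_qc.n_snps,
        "n_animals": geno_qc.n_individuals,
        "n_pruned_snps": len(pruned),
    }

    # --- stratification ----------------------------------------------
    G = build_G(geno_qc)
    n_pc = min(20, G.matrix.shape[0] - 1)
    scores, var_exp = pca(G, n_pc)
    clusters = kmeans_clusters(scores, n_pc_used=min(10, n_pc),
                               k=min(3, len(G.ids)), seed=cfg["seed"])
    pd.DataFrame({"animal": G.ids, "cluster": clusters,
                  **{f"PC{i + 1}": scores[:, i] for i in range(min(4, n_pc))}}
                 ).to_csv(outdir / "stratification.tsv", sep="\t", index=False)
    manifest["stages"]["stratification"] = {
        "pc1_var_explained": float(var_exp[0]),
        "cluster_sizes": np.bincount(clusters).tolist(),
    }

    # --- maternal animal model + GREML --------------------------------
    trait = sim_cfg.trait
    vc, fit = fit_maternal_model(pheno_qc, ped, trait)
    h2d, h2d_se = vc.ratio("direct")
    h2m, h2m_se = vc.ratio("maternal")
    param_rows = [{"parameter": k, "estimate": vc.estimates[k],
                   "se": vc.se[k]} for k in vc.param_names]
    param_rows += [{"parameter": "h2_direct", "estimate": h2d, "se": h2d_se},
                   {"parameter": "h2_maternal", "estimate": h2m, "se": h2m_se}]
    precorrected = precorrect_phenotypes(fit)
    geno_ids = set(geno_qc.individual_ids)
    pre_geno = precorrected[precorrected.index.isin(geno_ids)]
    vc_g = fit_greml(pre_geno, G.subset([a for a in G.ids
                                         if a in pre_geno.index]))
    h2g, h2g_se = vc_g.ratio("genomic")
    param_rows.append({"parameter": "h2_genomic", "estimate": h2g,
                       "se": h2g_se})
    pd.DataFrame(param_rows).to_csv(outdir / "variance_components.tsv",
                                    sep="\t", index=False)
    manifest["stages"]["reml"] = {"h2_direct": h2d, "h2_maternal": h2m,
                                  "h2_genomic": h2g, "loglik": vc.loglik}

    # --- breeding values and DRP --------------------------------------
    bvs = solve_mme(fit)
    drp_d = filter_drp(deregress(bvs, ped, h2d, c=cfg["drp_c"],
                                 effect="direct"))
    drp_m = filter_drp(deregress(bvs, ped, max(h2m, 0.01), c=cfg["drp_c"],
                                 effect="maternal"))
    drp_d.table.to_csv(outdir / "drp_direct.tsv", sep="\t", index=False)
    drp_m.table.to_csv(outdir / "drp_maternal.tsv", sep="\t", index=False)
    manifest["stages"]["drp"] = {
        "n_dDRP": int(drp_d.table["kept"].sum()),
        "n_mDRP": int(drp_m.table["kept"].sum()),
    }

    # --- association scans --------------------------------------------
    dep_data = {}
    if "phenotype" in cfg["dependents"]:
        dep_data["phenotype"] = (pheno_qc, None)
    min_records = 30
    for dep_name, drp_set in (("dDRP", drp_d), ("mDRP", drp_m)):
        if dep_name not in cfg["dependents"]:
            continue
        kept = drp_set.kept().set_index("animal")
        kept = kept[kept.index.isin(geno_ids)]
        if len(kept) < min_records:
            logger.warning("%s: only %d usable records after the weight "
                           "filter; scan skipped", dep_name, len(kept))
            continue
        dep_data[dep_name] = (kept["drp"], kept["weight"])

    grid_rows = []
    results = {}
    for dep_name, (dep, wts) in dep_data.items():
        for corr in cfg["corrections"]:
            scan = ScanConfig(dependent=dep_name, correction=corr,
                              trait=trait, alpha=cfg["alpha"])
            res = run_scan(geno_qc, dep, scan, ped=ped, weights=wts,
                           pruned_snps=pruned)
            results[(dep_name, corr)] = res
            res.table.to_csv(
                outdir / f"assoc_{dep_name}_{corr.replace('+', '_')}.tsv",
                sep="\t", index=False)
            grid_rows.append({"dependent": dep_name, "correction": corr,
                              "n_fdr": res.n_fdr,
                              "n_bonferroni": res.n_bonferroni,
                              "lambda": res.lambda_})
    grid = pd.DataFrame(grid_rows)
    grid.to_csv(outdir / "scan_summary.tsv", sep="\t", index=False)
    manifest["stages"]["gwas"] = grid.to_dict(orient="records")

    # direct-maternal effect correlations where both scans exist
    for corr in cfg["corrections"]:
        if ("dDRP", corr) in results and ("mDRP", corr) in results:
            cors = effect_correlations(results[("dDRP", corr)],
                                       results[("mDRP", corr)])
            cors.to_csv(outdir / f"effect_correlations_{corr}.tsv",
                        sep="\t", index=False)
            break

    # --- gene-based test ----------------------------------------------
    first = next(iter(results.values()))
    mapping = map_snps_to_genes(geno_qc.snp_map, genes)
    gene_results = gene_test(mapping, first, alpha=cfg["alpha"])
    gene_results.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)
    manifest["stages"]["genes"] = {
        "n_tested": len(gene_results),
        "n_significant": int(gene_results["significant"].sum())
        if len(gene_results) else 0,
    }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def report(outdir) -> str:
    """Human-readable summary of a completed run."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    lines = [f"run {manifest['config_hash']} (seed {manifest['seed']})"]
    vc = pd.read_csv(outdir / "variance_components.tsv", sep="\t")
    lines.append("\nvariance components / heritabilities:")
    lines.append(vc.to_string(index=False))
    grid = pd.read_csv(outdir / "scan_summary.tsv", sep="\t")
    lines.append("\nassociation scans (dependent x correction):")
    lines.append(grid.to_string(index=False))
    return "\n".join(lines)
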