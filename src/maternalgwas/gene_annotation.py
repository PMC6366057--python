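"""Windowed SNP-to-gene mapping and the Fisher combination gene test.

A SNP maps to a gene when it lies on the same chromosome within a
closed window extending 100 kb beyond both gene ends. Each gene's
statistic sums ``-2 ln(p)`` over its mapped SNPs and is referred to a
chi-square distribution with ``2 k`` df (Fisher's method; the natural
logarithm is required for that null). Gene-level significance is
controlled by Benjamini-Hochberg FDR at 5% over the tested genes.

Under linkage disequilibrium between mapped SNPs the independence
chi-square is anti-conservative; the test reproduces that behaviour
deliberately (no LD-aware adjustment is applied).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import AssociationResult, multiple_testing
from .io_formats import GeneTable

logger = logging.getLogger(__name__)

__all__ = ["map_snps_to_genes", "gene_test", "DEFAULT_WINDOW_BP"]

DEFAULT_WINDOW_BP = 100_000


def map_snps_to_genes(snp_map: pd.DataFrame, genes: GeneTable,
                      window_bp: int = DEFAULT_WINDOW_BP) -> dict:
    """Map each gene to the SNP ids inside its windowed interval.

    The interval ``[start - window, end + window]`` is closed and
    1-based; a SNP may map to several overlapping genes. Returns
    ``{gene_id: [snp ids]}`` including empty lists for SNP-free genes.
    """
    mapping: dict[str, list[str]] = {}
    by_chrom = {c: g for c, g in snp_map.groupby("chrom")}
    for rec in genes.records.itertuples():
        sub = by_chrom.get(rec.chrom)
        if sub is None:
            mapping[rec.gene_id] = []
            continue
        pos = sub["pos"].to_numpy()
        inside = (pos >= rec.start_bp - window_bp) & \
                 (pos <= rec.end_bp + window_bp)
        mapping[rec.gene_id] = sub.loc[inside, "snp"].tolist()
    return mapping


def gene_test(mapping: dict, assoc: AssociationResult,
              alpha: float = 0.05) -> pd.DataFrame:
    """Fisher combination test per gene with FDR control.

    Genes with zero mapped SNPs are left untested (and excluded from
    the FDR family). SNP p-values of exactly zero are floored at the
    smallest positive float with a warning.
    """
    p_of = assoc.table.set_index("snp")["p"]
    rows = []
    floored = 0
    for gene_id, snps in mapping.items():
        snps = [s for s in snps if s in p_of.index]
        k = len(snps)
        if k == 0:
            continue
        p = p_of.loc[snps].to_numpy(float)
        if (p <= 0).any():
            floored += int((p <= 0).sum())
            p = np.maximum(p, np.finfo(float).tiny)
        stat = float(np.sum(-2.0 * np.log(p)))
        df = 2 * k
        rows.append({"gene_id": gene_id, "n_snps": k, "statistic": stat,
                     "df": df, "p": float(stats.chi2.sf(stat, df))})
    if floored:
        logger.warning("%d SNP p-value(s) of zero floored at the smallest "
                       "positive float", floored)
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_snps", "statistic", "df",
                                     "p", "p_fdr", "significant"])
    out = pd.DataFrame(rows)
    _, p_adj, flags = multiple_testing(out["p"].to_numpy(), alpha=alpha)
    out["p_fdr"] = p_adj
    out["significant"] = flags
    return out
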