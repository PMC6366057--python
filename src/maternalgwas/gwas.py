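"""Single-marker mixed-model association under the population-structure
correction schemes, with inflation diagnostics and multiple testing.

The scan (mixed-linear-model association, MLMA) tests each SNP as a
fixed covariate in ``y = Xb + g w + u + e`` with ``u ~ (0, K sigma_u2)``;
variance components are estimated once per null model (never per SNP)
and the SNP effect is a generalized-least-squares solve at the null
ratio. The similarity matrix ``K`` can be the pedigree matrix, the
full genomic matrix, a leave-one-chromosome-out (LOCO) or
leave-one-segment-out genomic matrix, optionally combined with global
or chromosome-wide principal components as covariates. With
``correction="none"`` each SNP is an ordinary least-squares regression
(exact t-test), the classic naive scan whose inflation the corrections
are judged against.

The genomic inflation factor is ``lambda = median(chi2) / 0.4549``,
the denominator being the median of the 1-df chi-square distribution.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenotypeMatrix, Pedigree, PhenotypeTable, \
    ValidationError
from .kinship import (RelationshipMatrix, build_A, build_G, build_chrom_G,
                      build_loco, make_segment_scheme, pca)
from .qc import _fixed_effect_design
from .reml import SingleKernelFit, fit_single_kernel_reml

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df — the denominator of
#: the inflation-factor formula (0.4549 at the printed precision).
CHI2_1_MEDIAN = float(stats.chi2(1).median())

CORRECTIONS = ("none", "A", "G", "LOCO", "LOCO_prune", "LOCO_SEG40",
               "LOCO_SEG441", "LOCO_SEG864", "LOCO+PC20", "LOCO+CHR_PC3",
               "LOCO+CHR_PC10", "LOCO+CHR_PC20")


@dataclasses.dataclass
class ScanConfig:
    """What to scan and how to correct for structure."""

    dependent: str = "phenotype"        # phenotype | dDRP | mDRP
    correction: str = "G"
    trait: str = "BW0"
    use_weights: bool = True            # DRP weights as inverse residual weights
    n_pc_global: int = 20
    alpha: float = 0.05

    def __post_init__(self):
        if self.correction not in CORRECTIONS:
            raise ValidationError(f"unknown correction {self.correction!r}")


@dataclasses.dataclass
class NullFit:
    """A no-SNP model: REML polygenic fit, or OLS when K is absent."""

    skf: SingleKernelFit | None
    X: np.ndarray
    y: np.ndarray
    label: str = ""

    @property
    def h2(self):
        return self.skf.h2 if self.skf is not None else 0.0


@dataclasses.dataclass
class AssociationResult:
    """Per-SNP effects and the scan-level diagnostics."""

    table: pd.DataFrame     # snp, chrom, pos, freq, effect, se, chi2, p, ...
    lambda_: float
    n_bonferroni: int
    n_fdr: int
    bonferroni_threshold: float
    correction: str = ""

    def __post_init__(self):
        t = self.table
        tested = t.loc[~t["monomorphic"]]
        if len(tested) and not ((tested["p"] > 0) & (tested["p"] <= 1)).all():
            raise ValidationError("p-values outside (0, 1]")


def fit_null(y, X, K=None, weights=None, label="") -> NullFit:
    """Fit the no-SNP model once; duplicate covariate columns are dropped."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    keep = diag > 1e-8 * max(1.0, diag.max())
    if not keep.all():
        logger.warning("dropping %d collinear covariate column(s)",
                       int((~keep).sum()))
        cols, basis = [], np.zeros((X.shape[0], 0))
        for j in range(X.shape[1]):
            trial = np.hstack([basis, X[:, j:j + 1]])
            if np.linalg.matrix_rank(trial) > basis.shape[1]:
                basis, cols = trial, cols + [j]
        X = X[:, cols]
    if K is None:
        return NullFit(None, X, y, label)
    Km = K.matrix if isinstance(K, RelationshipMatrix) else np.asarray(K)
    return NullFit(fit_single_kernel_reml(y, X, Km, weights=weights),
                   X, y, label)


def _test_batch(null: NullFit, G_cols: np.ndarray, ols: bool):
    """GLS (or OLS) effect, SE and Wald statistic for a dosage batch."""
    if null.skf is not None:
        skf = null.skf
        v = skf.marginal_variances
        w = 1.0 / v
        Xs = skf.rotated_X
        ys = skf.rotated_y
        Gs = skf.U.T @ (G_cols * skf.sqrt_w[:, None])
    else:
        w = np.ones(len(null.y))
        Xs, ys, Gs = null.X, null.y, G_cols
    Xw = Xs * w[:, None]
    Cxx = Xs.T @ Xw
    Cxx_inv = np.linalg.inv(Cxx)
    xty = Xw.T @ ys
    alpha = Cxx_inv @ xty
    yMy = float(np.sum(ys ** 2 * w) - xty @ alpha)
    Cg = Xw.T @ Gs                               # p x m
    gwg = np.einsum("ij,ij->j", Gs, Gs * w[:, None])
    gMg = gwg - np.einsum("ij,ij->j", Cg, Cxx_inv @ Cg)
    gwy = Gs.T @ (ys * w)
    gMy = gwy - Cg.T @ alpha
    ok = gMg > 1e-10
    effect = np.full(Gs.shape[1], np.nan)
    se = np.full(Gs.shape[1], np.nan)
    chi2 = np.zeros(Gs.shape[1])
    p = np.ones(Gs.shape[1])
    effect[ok] = gMy[ok] / gMg[ok]
    if not ols:
        se[ok] = np.sqrt(1.0 / gMg[ok])
        chi2[ok] = gMy[ok] ** 2 / gMg[ok]
        p[ok] = stats.chi2.sf(chi2[ok], df=1)
    else:
        n, p_cols = null.X.shape
        dof = n - p_cols - 1
        if dof <= 0:
            raise ValidationError("no residual df for the naive scan")
        rss = yMy - gMy[ok] ** 2 / gMg[ok]
        s2 = np.maximum(rss / dof, 1e-300)
        se[ok] = np.sqrt(s2 / gMg[ok])
        tstat2 = effect[ok] ** 2 / (s2 / gMg[ok])
        chi2[ok] = tstat2
        p[ok] = 2.0 * stats.t.sf(np.sqrt(tstat2), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return effect, se, chi2, p, ~ok


def mlma_scan(geno: GenotypeMatrix, fits, allele_freqs=None,
              alpha: float = 0.05, correction: str = "",
              ols: bool = False) -> AssociationResult:
    """Scan all SNPs, each against the null fit covering its target.

    ``fits`` is a list of ``(NullFit, snp_index_array)`` pairs whose
    index arrays jointly cover each tested SNP exactly once (for a
    single-matrix correction that is one pair covering everything).
    Missing dosages are mean-imputed at 2p; monomorphic SNPs yield
    p = 1 with a flag.
    """
    if allele_freqs is None:
        allele_freqs = geno.allele_frequencies()
    freq = np.nan_to_num(np.asarray(allele_freqs, dtype=float), nan=0.0)
    m = geno.n_snps
    effect = np.full(m, np.nan)
    se = np.full(m, np.nan)
    chi2 = np.zeros(m)
    p = np.ones(m)
    mono = np.zeros(m, dtype=bool)
    covered = np.zeros(m, dtype=bool)
    for null, snp_idx in fits:
        snp_idx = np.asarray(snp_idx, dtype=int)
        if covered[snp_idx].any():
            raise ValidationError("a SNP is covered by two null fits")
        covered[snp_idx] = True
        d = geno.dosages[:, snp_idx]
        centre = 2.0 * freq[snp_idx]
        nan = np.isnan(d)
        if nan.any():
            d = np.where(nan, np.broadcast_to(centre, d.shape), d)
        e, s, c2, pv, bad = _test_batch(null, d, ols)
        effect[snp_idx], se[snp_idx] = e, s
        chi2[snp_idx], p[snp_idx] = c2, pv
        mono[snp_idx] = bad
    if not covered.all():
        raise ValidationError("null fits do not cover every SNP")

    table = geno.snp_map.copy()
    table["freq"] = freq
    table["effect"] = effect
    table["se"] = se
    table["chi2"] = chi2
    table["p"] = p
    table["monomorphic"] = mono
    tested = ~mono
    lam = inflation_factor(chi2[tested]) if tested.any() else np.nan
    bonf_thr, p_fdr, fdr_sig = multiple_testing(p[tested], alpha=alpha)
    table["p_fdr"] = np.nan
    table.loc[tested, "p_fdr"] = p_fdr
    table["bonf_sig"] = False
    table.loc[tested, "bonf_sig"] = p[tested] < bonf_thr
    table["fdr_sig"] = False
    table.loc[tested, "fdr_sig"] = fdr_sig
    return AssociationResult(
        table=table, lambda_=float(lam),
        n_bonferroni=int(table["bonf_sig"].sum()),
        n_fdr=int(table["fdr_sig"].sum()),
        bonferroni_threshold=float(bonf_thr),
        correction=correction)


# ---------------------------------------------------------------------------
# correction schemes
# ---------------------------------------------------------------------------

def _chrom_indices(snp_map: pd.DataFrame) -> dict:
    return {int(c): np.flatnonzero(snp_map["chrom"].to_numpy() == c)
            for c in snp_map["chrom"].unique()}


def run_scan(geno: GenotypeMatrix, dependent, scan: ScanConfig,
             ped: Pedigree | None = None, weights=None,
             pruned_snps=None) -> AssociationResult:
    """Assemble the null fits required by ``scan.correction`` and run.

    ``dependent`` is either a :class:`PhenotypeTable` (Model-style
    fixed effects for ``scan.trait``) or a series keyed by animal
    (overall mean only, the DRP case). ``weights`` (a series keyed by
    animal) enter the residual covariance as ``diag(1/w) sigma_e2``
    when ``scan.use_weights`` is set.
    """
    if isinstance(dependent, PhenotypeTable):
        df = dependent.for_trait(scan.trait)
        df = df[df["animal"].isin(geno.individual_ids)]
        ids = df["animal"].tolist()
        y = df["weight_kg"].to_numpy(float)
        X = _fixed_effect_design(df)
    else:
        s = pd.Series(dependent).dropna()
        ids = [a for a in geno.individual_ids if a in s.index]
        y = s.reindex(ids).to_numpy(float)
        X = np.ones((len(ids), 1))
    w = None
    if weights is not None and scan.use_weights:
        w = pd.Series(weights).reindex(ids).to_numpy(float)
        if np.isnan(w).any():
            raise ValidationError("missing DRP weight for an analyzed animal")

    sub = geno.subset(individuals=ids)
    if scan.correction == "LOCO_prune":
        if pruned_snps is None:
            raise ValidationError("LOCO_prune requires the pruned SNP list")
        sub = sub.subset(snps=pruned_snps)
    freqs = sub.allele_frequencies()
    chrom_idx = _chrom_indices(sub.snp_map)
    corr = scan.correction

    fits = []
    ols = False
    if corr == "none":
        fits = [(fit_null(y, X, None, label="none"), np.arange(sub.n_snps))]
        ols = True
    elif corr == "A":
        if ped is None:
            raise ValidationError("correction 'A' requires a pedigree")
        K = build_A(ped, ids=ids)
        fits = [(fit_null(y, X, K, w, label="A"), np.arange(sub.n_snps))]
    elif corr == "G":
        K = build_G(sub, allele_freqs=freqs)
        fits = [(fit_null(y, X, K, w, label="G"), np.arange(sub.n_snps))]
    elif corr in ("LOCO", "LOCO_prune"):
        for c, idx in chrom_idx.items():
            K = build_loco(sub, c, allele_freqs=freqs)
            fits.append((fit_null(y, X, K, w, label=f"LOCO{c}"), idx))
    elif corr in ("LOCO_SEG40", "LOCO_SEG441", "LOCO_SEG864"):
        scheme = make_segment_scheme(sub.snp_map, corr.replace("LOCO_", ""))
        snp_pos = {s: j for j, s in enumerate(sub.snp_map["snp"])}
        for seg_id, _, seg_snps in scheme.segments:
            idx = np.array([snp_pos[s] for s in seg_snps], dtype=int)
            K = build_loco(sub, seg_snps, allele_freqs=freqs,
                           label=f"G_loco_seg({seg_id})")
            fits.append((fit_null(y, X, K, w, label=seg_id), idx))
    elif corr == "LOCO+PC20":
        G_full = build_G(sub, allele_freqs=freqs)
        scores, _ = pca(G_full, min(scan.n_pc_global, len(ids) - 1))
        Xpc = np.hstack([X, scores])
        for c, idx in chrom_idx.items():
            K = build_loco(sub, c, allele_freqs=freqs)
            fits.append((fit_null(y, Xpc, K, w, label=f"LOCO+PC20:{c}"), idx))
    elif corr.startswith("LOCO+CHR_PC"):
        k = int(corr.replace("LOCO+CHR_PC", ""))
        for c, idx in chrom_idx.items():
            Gc = build_chrom_G(sub, c, allele_freqs=freqs)
            scores, _ = pca(Gc, min(k, len(ids) - 1))
            Xpc = np.hstack([X, scores[:, :k]])
            K = build_loco(sub, c, allele_freqs=freqs)
            fits.append((fit_null(y, Xpc, K, w, label=f"{corr}:{c}"), idx))
    return mlma_scan(sub, fits, allele_freqs=freqs, alpha=scan.alpha,
                     correction=corr, ols=ols)


# ---------------------------------------------------------------------------
# scan-level statistics
# ---------------------------------------------------------------------------

def inflation_factor(wald_chi2) -> float:
    """Median-based genomic inflation: median(chi2) / chi2_1 median."""
    arr = np.asarray(wald_chi2, dtype=float)
    if arr.size == 0:
        raise ValidationError("no statistics to compute lambda from")
    return float(np.median(arr) / CHI2_1_MEDIAN)


def multiple_testing(p, alpha: float = 0.05):
    """Bonferroni threshold and Benjamini-Hochberg adjusted p-values.

    Returns ``(bonferroni_threshold, fdr_adjusted_p, fdr_flags)`` with
    the threshold ``alpha / N`` and FDR significance at adjusted
    p < alpha.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    bonf_thr = alpha / n if n else alpha
    if n == 0:
        return bonf_thr, np.array([]), np.array([], dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return bonf_thr, p_adj, p_adj < alpha


def variance_explained(effect: float, allele_freq: float,
                       var_dependent: float) -> float:
    """Fraction of dependent-variable variance a SNP explains:
    ``2 p (1-p) g^2 / var``."""
    if var_dependent <= 0:
        raise ValidationError("dependent variance must be positive")
    if not 0 < allele_freq < 1:
        raise ValidationError("allele frequency must be in (0, 1)")
    return 2.0 * allele_freq * (1.0 - allele_freq) * effect ** 2 / var_dependent


def effect_correlations(res_d: AssociationResult, res_m: AssociationResult,
                        region: tuple | None = None) -> pd.DataFrame:
    """Pearson correlations between direct and maternal SNP effects.

    Rows: genome-wide, one per chromosome, and optionally a bp-window
    region given as ``(chrom, start_bp, end_bp)``. Strata with fewer
    than 3 shared SNPs are omitted with a log message.
    """
    t_d = res_d.table.set_index("snp")
    t_m = res_m.table.set_index("snp")
    shared = t_d.index.intersection(t_m.index)
    d = t_d.loc[shared]
    m = t_m.loc[shared]
    ok = (~d["effect"].isna()) & (~m["effect"].isna())
    d, m = d.loc[ok], m.loc[ok]

    def corr(mask, label):
        if mask.sum() < 3:
            logger.warning("stratum %s has < 3 shared SNPs; omitted", label)
            return None
        r = float(np.corrcoef(d.loc[mask, "effect"],
                              m.loc[mask, "effect"])[0, 1])
        return {"stratum": label, "n_snps": int(mask.sum()), "correlation": r}

    rows = [corr(pd.Series(True, index=d.index), "genome")]
    for c in sorted(d["chrom"].unique()):
        rows.append(corr(d["chrom"] == c, f"chr{c}"))
    if region is not None:
        c, lo, hi = region
        mask = (d["chrom"] == c) & (d["pos"] >= lo) & (d["pos"] <= hi)
        rows.append(corr(mask, f"chr{c}:{lo}-{hi}"))
    return pd.DataFrame([r for r in rows if r is not None])
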