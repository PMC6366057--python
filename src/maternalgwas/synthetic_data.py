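"""Synthetic half-sib cattle populations with maternally influenced weights.

The generator emulates the salient structure of a Holstein-style
paternal half-sib population: a handful of sires with highly skewed
daughter-group sizes (one family can dominate the genotyped set), 29
autosomes of biallelic SNPs with tunable adjacent-marker LD, and body
weights generated under the maternal animal model

    y = herd + year + month + slope * covariate + u_animal + m_dam
        + pe_dam + e,

with (u, m) drawn jointly from the pedigree (infinitesimal mode) or
from causal SNPs (QTL mode). Ground truth is returned for recovery
tests.

Haplotypes are first-order Markov chains: a latent AR(1) Gaussian with
lag correlation ``adjacent_ld_rho`` is thresholded at each locus's
allele frequency, which creates decaying LD along the chromosome.
Gametes are transmitted as whole-chromosome blocks (no recombination
within a simulated meiosis); family covariance, not fine-scale linkage,
is the structure under study.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (FOUNDER, GeneTable, GenotypeMatrix, Pedigree,
                         PhenotypeTable, ValidationError)

__all__ = ["SimConfig", "SimTruth", "simulate_population",
           "simulate_phenotypes", "simulate_gene_table"]


@dataclasses.dataclass
class SimConfig:
    """Parameters of the simulated population and trait.

    Variance defaults are birth-weight-like: phenotypic variance 25 kg^2
    split as 46% direct genetic, 14% maternal genetic, 5% maternal
    permanent environment and 35% residual. Gestation length (the BW0
    covariate) averages 279.4 days within 265-295.
    """

    n_sires: int = 5
    daughters_per_sire: list[int] = dataclasses.field(
        default_factory=lambda: [400, 100, 50, 25, 25])
    n_chromosomes: int = 29
    snps_per_chromosome: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    adjacent_ld_rho: float = 0.5
    chromosome_length_bp: int = 100_000_000
    var_direct: float = 11.5
    var_maternal: float = 3.5
    cov_direct_maternal: float = 0.0
    var_mat_pe: float = 1.25
    var_residual: float = 8.75
    n_qtl_direct: int = 0
    n_qtl_maternal: int = 0
    qtl_chromosomes: tuple | None = None   # restrict causal SNPs, None = all
    n_herds: int = 5
    n_years: int = 3
    n_months: int = 12
    covariate_slope: float = 0.25
    fixed_effect_sd: float = 2.0
    base_weight_kg: float = 40.0
    trait: str = "BW0"
    gestation_mean_days: float = 279.4
    gestation_range: tuple[float, float] = (265.0, 295.0)
    dam_genotyped_fraction: float = 0.5
    offspring_per_dam: int = 2
    dams_per_grandsire: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.daughters_per_sire) != self.n_sires:
            raise ValidationError(
                "daughters_per_sire must have one entry per sire")
        g0 = self.genetic_covariance
        if np.linalg.eigvalsh(g0).min() < -1e-12:
            raise ValidationError(
                "direct/maternal genetic covariance matrix is not PSD")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValidationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.adjacent_ld_rho < 1):
            raise ValidationError("adjacent_ld_rho must be in [0, 1)")
        for name in ("var_direct", "var_maternal", "var_mat_pe", "var_residual"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def genetic_covariance(self) -> np.ndarray:
        return np.array([[self.var_direct, self.cov_direct_maternal],
                         [self.cov_direct_maternal, self.var_maternal]])

    @property
    def n_daughters(self) -> int:
        return int(sum(self.daughters_per_sire))

    @property
    def var_phenotypic(self) -> float:
        return (self.var_direct + self.var_maternal + self.var_mat_pe
                + self.var_residual + self.cov_direct_maternal)


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    variance_components: dict
    genetic_values: pd.DataFrame    # animal, u, m
    pe_values: pd.Series            # dam -> permanent environment effect
    residuals: pd.Series            # record animal -> e
    fixed_part: pd.Series           # record animal -> fixed-effect contribution
    causal_direct: pd.DataFrame     # snp, effect
    causal_maternal: pd.DataFrame
    sire_of: pd.Series              # daughter -> sire


# ---------------------------------------------------------------------------
# genotypes and pedigree
# ---------------------------------------------------------------------------

def _haplotypes(rng, n_hap, freqs_by_chrom, rho):
    """Markov haplotypes: thresholded latent AR(1) per chromosome."""
    out = []
    for freqs in freqs_by_chrom:
        m = len(freqs)
        z = np.empty((n_hap, m))
        z[:, 0] = rng.standard_normal(n_hap)
        if m > 1:
            innov = rng.standard_normal((n_hap, m - 1)) * np.sqrt(1 - rho ** 2)
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
        thresh = stats.norm.ppf(freqs)
        out.append((z < thresh).astype(np.int8))
    return np.hstack(out)


def simulate_population(config: SimConfig):
    """Simulate genotypes and pedigree for a skewed half-sib population.

    Returns ``(geno, ped)``. The genotype matrix covers every animal
    (sires, dams, daughters); the pedigree carries a ``genotyped``
    column marking the subset a genotyping study would observe (all
    sires and daughters, plus a configurable fraction of dams), which
    :func:`genotyped_ids` extracts.
    """
    rng = np.random.default_rng(config.seed)
    n_c, m_c = config.n_chromosomes, config.snps_per_chromosome

    freqs_by_chrom = [
        rng.uniform(*config.maf_range, size=m_c) for _ in range(n_c)]
    positions = [np.sort(rng.integers(1, config.chromosome_length_bp + 1,
                                      size=m_c)) for _ in range(n_c)]
    snp_map = pd.DataFrame({
        "snp": [f"snp{c + 1}_{j + 1}" for c in range(n_c) for j in range(m_c)],
        "chrom": np.repeat(np.arange(1, n_c + 1), m_c),
        "pos": np.concatenate(positions),
        "a1": "A",
        "a2": "B",
    })
    # duplicate positions within a chromosome would break (chrom, pos) keys
    for c in range(n_c):
        seg = snp_map.loc[snp_map["chrom"] == c + 1, "pos"].to_numpy()
        snp_map.loc[snp_map["chrom"] == c + 1, "pos"] = (
            seg + np.arange(len(seg)))

    # dams form half-sib groups under maternal grandsires, nested within
    # each paternal family (dam groups are mated to one sire, as in the
    # clustered half-sib structure the generator emulates); the maternal
    # pedigree links are what identify maternal genetic variance
    sires = [f"S{i + 1}" for i in range(config.n_sires)]
    daughters, dams, mgsires = [], [], []
    sire_of, dam_of, mgs_of = {}, {}, {}
    for s, n_d in zip(sires, config.daughters_per_sire):
        remaining = n_d
        fam_dams = 0
        while remaining > 0:
            dam = f"D{len(dams) + 1}"
            if fam_dams % config.dams_per_grandsire == 0:
                mgsires.append(f"M{len(mgsires) + 1}")
            mgs_of[dam] = mgsires[-1]
            dams.append(dam)
            fam_dams += 1
            for _ in range(min(config.offspring_per_dam, remaining)):
                child = f"C{len(daughters) + 1}"
                daughters.append(child)
                sire_of[child] = s
                dam_of[child] = dam
                remaining -= 1
    n_mgs = len(mgsires)

    chrom_slices = [slice(c * m_c, (c + 1) * m_c) for c in range(n_c)]
    n_snp = n_c * m_c

    def _founder_pair(n):
        h = _haplotypes(rng, 2 * n, freqs_by_chrom, config.adjacent_ld_rho)
        return h.reshape(n, 2, -1)

    def _gamete(parent_hap):
        g = np.empty(n_snp, dtype=np.int8)
        pick = rng.integers(0, 2, size=n_c)
        for c, sl in enumerate(chrom_slices):
            g[sl] = parent_hap[pick[c], sl]
        return g

    sire_h = _founder_pair(len(sires))
    mgs_h = _founder_pair(n_mgs)
    sire_pos = {s: i for i, s in enumerate(sires)}
    mgs_pos = {g: i for i, g in enumerate(mgsires)}
    dam_h = np.empty((len(dams), 2, n_snp), dtype=np.int8)
    dam_pop = _haplotypes(rng, len(dams), freqs_by_chrom,
                          config.adjacent_ld_rho)
    for i, d in enumerate(dams):
        dam_h[i, 0] = _gamete(mgs_h[mgs_pos[mgs_of[d]]])
        dam_h[i, 1] = dam_pop[i]
    dam_pos = {d: i for i, d in enumerate(dams)}

    rows = {s: sire_h[i, 0] + sire_h[i, 1] for s, i in sire_pos.items()}
    rows.update({g: mgs_h[i, 0] + mgs_h[i, 1] for g, i in mgs_pos.items()})
    rows.update({d: dam_h[i, 0] + dam_h[i, 1] for d, i in dam_pos.items()})
    for child in daughters:
        rows[child] = (_gamete(sire_h[sire_pos[sire_of[child]]])
                       + _gamete(dam_h[dam_pos[dam_of[child]]]))

    all_ids = sires + mgsires + dams + daughters
    dosages = np.vstack([rows[a] for a in all_ids]).astype(np.float64)
    geno = GenotypeMatrix(dosages, all_ids, snp_map)

    dam_flags = rng.random(len(dams)) < config.dam_genotyped_fraction
    genotyped = {**{s: False for s in sires + mgsires},
                 **{d: bool(f) for d, f in zip(dams, dam_flags)},
                 **{c: True for c in daughters}}
    n_founders = len(sires) + len(mgsires)
    ped = Pedigree(pd.DataFrame({
        "animal": all_ids,
        "sire": [FOUNDER] * n_founders + [mgs_of[d] for d in dams]
                + [sire_of[c] for c in daughters],
        "dam": [FOUNDER] * (n_founders + len(dams))
               + [dam_of[c] for c in daughters],
        "birth_year": [1995] * n_founders + [2000] * len(dams)
                      + list(rng.integers(2005, 2005 + config.n_years,
                                          size=len(daughters))),
    }))
    ped.records["genotyped"] = ped.records["animal"].map(genotyped)
    return geno, ped


def genotyped_ids(ped: Pedigree) -> list[str]:
    """Animals flagged as genotyped by :func:`simulate_population`."""
    df = ped.records
    if "genotyped" not in df.columns:
        return df["animal"].tolist()
    return df.loc[df["genotyped"].astype(bool), "animal"].tolist()


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _infinitesimal_values(ped: Pedigree, g0: np.ndarray, rng) -> pd.DataFrame:
    """Joint (u, m) by parent-average + Mendelian-sampling recursion."""
    chol = np.linalg.cholesky(g0 + 1e-12 * np.eye(2))
    values: dict[str, np.ndarray] = {}
    rec = ped.records.set_index("animal")
    for a in ped.animals:
        s = rec.loc[a, "sire"] if a in rec.index else FOUNDER
        d = rec.loc[a, "dam"] if a in rec.index else FOUNDER
        pa = np.zeros(2)
        n_known = 0
        for p in (s, d):
            if p in values:
                pa += 0.5 * values[p]
                n_known += 1
        mend_frac = 1.0 - 0.25 * n_known
        values[a] = pa + np.sqrt(mend_frac) * (chol @ rng.standard_normal(2))
    df = pd.DataFrame(values).T
    df.columns = ["u", "m"]
    df.index.name = "animal"
    return df


def _qtl_values(geno: GenotypeMatrix, n_qtl: int, target_var: float,
                rng, chromosomes=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Genetic values from causal SNPs, rescaled to the exact variance."""
    if chromosomes is None:
        candidates = np.arange(geno.n_snps)
    else:
        candidates = np.flatnonzero(
            geno.snp_map["chrom"].isin(chromosomes).to_numpy())
    if n_qtl > candidates.size:
        raise ValidationError("more QTL requested than SNPs available")
    idx = np.sort(rng.choice(candidates, size=n_qtl, replace=False))
    beta = rng.standard_normal(n_qtl)
    M = np.nan_to_num(geno.dosages[:, idx], nan=0.0)
    g = (M - M.mean(axis=0)) @ beta
    sd = g.std()
    scale = np.sqrt(target_var) / sd if sd > 0 else 0.0
    g = g * scale
    causal = pd.DataFrame({"snp": geno.snp_map["snp"].to_numpy()[idx],
                           "effect": beta * scale})
    return g, causal


def simulate_phenotypes(geno: GenotypeMatrix, ped: Pedigree,
                        config: SimConfig):
    """Generate maternal-model phenotypes for every animal with a known dam.

    Returns ``(pheno, truth)``. In infinitesimal mode (``n_qtl_* = 0``)
    the joint (u, m) values propagate through the pedigree; in QTL mode
    they are built from causal SNPs with effects rescaled so the
    realized variances hit the configured values exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    rec = ped.records
    # the youngest generation carries records: known-sire animals that
    # are not themselves parents
    parents = set(rec["sire"]) | set(rec["dam"])
    phenotyped = rec.loc[(rec["sire"] != FOUNDER)
                         & ~rec["animal"].isin(parents), "animal"].tolist()
    dams_of = dict(zip(rec["animal"], rec["dam"]))
    if config.var_maternal > 0 or config.var_mat_pe > 0:
        unknown = [a for a in phenotyped if dams_of.get(a, FOUNDER) == FOUNDER]
        if unknown:
            raise ValidationError(
                f"phenotyped animal {unknown[0]} has an unknown dam but "
                "maternal variance is positive")

    causal_d = pd.DataFrame(columns=["snp", "effect"])
    causal_m = pd.DataFrame(columns=["snp", "effect"])
    if config.n_qtl_direct > 0 or config.n_qtl_maternal > 0:
        u = np.zeros(geno.n_individuals)
        m = np.zeros(geno.n_individuals)
        if config.n_qtl_direct > 0 and config.var_direct > 0:
            u, causal_d = _qtl_values(geno, config.n_qtl_direct,
                                      config.var_direct, rng,
                                      config.qtl_chromosomes)
        if config.n_qtl_maternal > 0 and config.var_maternal > 0:
            m, causal_m = _qtl_values(geno, config.n_qtl_maternal,
                                      config.var_maternal, rng,
                                      config.qtl_chromosomes)
        gv = pd.DataFrame({"u": u, "m": m}, index=geno.individual_ids)
        gv.index.name = "animal"
    else:
        gv = _infinitesimal_values(ped, config.genetic_covariance, rng)

    dams = sorted({dams_of[a] for a in phenotyped if dams_of[a] != FOUNDER})
    pe = pd.Series(rng.normal(0.0, np.sqrt(config.var_mat_pe), len(dams)),
                   index=dams)

    herd_eff = rng.normal(0, config.fixed_effect_sd, config.n_herds)
    year_eff = rng.normal(0, config.fixed_effect_sd, config.n_years)
    month_eff = rng.normal(0, config.fixed_effect_sd / 2, config.n_months)

    n = len(phenotyped)
    herd = rng.integers(0, config.n_herds, n)
    year = rec.set_index("animal").loc[phenotyped, "birth_year"].to_numpy()
    year_idx = (year - year.min()) % config.n_years
    month = rng.integers(0, config.n_months, n)
    if config.trait == "BW0":
        lo, hi = config.gestation_range
        sd = (hi - lo) / 6.0
        cov = np.clip(rng.normal(config.gestation_mean_days, sd, n), lo, hi)
    else:
        cov = rng.uniform(60, 120, n) if config.trait == "BW23" \
            else rng.uniform(390, 440, n)

    e = rng.normal(0.0, np.sqrt(config.var_residual), n)
    u_vec = gv["u"].reindex(phenotyped).to_numpy()
    dam_vec = [dams_of[a] for a in phenotyped]
    m_vec = gv["m"].reindex(dam_vec).to_numpy()
    m_vec = np.nan_to_num(m_vec)
    pe_vec = pe.reindex(dam_vec).to_numpy()
    fixed = (config.base_weight_kg + herd_eff[herd] + year_eff[year_idx]
             + month_eff[month]
             + config.covariate_slope * (cov - cov.mean()))
    y = fixed + u_vec + m_vec + pe_vec + e

    pheno = PhenotypeTable(pd.DataFrame({
        "animal": phenotyped,
        "trait": config.trait,
        "weight_kg": y,
        "herd": [f"H{h + 1}" for h in herd],
        "birth_year": year,
        "birth_month": month + 1,
        "covariate": cov,
    }))
    truth = SimTruth(
        variance_components={
            "var_direct": config.var_direct,
            "var_maternal": config.var_maternal,
            "cov_direct_maternal": config.cov_direct_maternal,
            "var_mat_pe": config.var_mat_pe,
            "var_residual": config.var_residual,
        },
        genetic_values=gv,
        pe_values=pe,
        residuals=pd.Series(e, index=phenotyped),
        fixed_part=pd.Series(fixed, index=phenotyped),
        causal_direct=causal_d,
        causal_maternal=causal_m,
        sire_of=pd.Series({a: rec.set_index("animal").loc[a, "sire"]
                           for a in phenotyped}),
    )
    return pheno, truth


def simulate_gene_table(config: SimConfig, n_genes: int = 50,
                        mean_length_bp: int = 50_000,
                        seed=None) -> GeneTable:
    """Random, possibly overlapping gene intervals on the simulated map."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    if n_genes == 0:
        return GeneTable(pd.DataFrame(
            columns=["gene_id", "chrom", "start_bp", "end_bp"]))
    chrom = rng.integers(1, config.n_chromosomes + 1, n_genes)
    length = rng.exponential(mean_length_bp, n_genes).astype(int) + 1000
    start = rng.integers(1, config.chromosome_length_bp, n_genes)
    end = np.minimum(start + length, config.chromosome_length_bp)
    df = pd.DataFrame({
        "gene_id": [f"GENE{i + 1}" for i in range(n_genes)],
        "chrom": chrom, "start_bp": start, "end_bp": end,
    }).sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    return GeneTable(df)
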