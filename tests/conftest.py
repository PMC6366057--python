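import numpy as np
import pandas as pd
import pytest

import maternalgwas as mg


@pytest.fixture(scope="session")
def small_population():
    """Three skewed half-sib families, 3 chromosomes, with phenotypes."""
    cfg = mg.SimConfig(n_sires=3, daughters_per_sire=[100, 40, 40],
                       n_chromosomes=3, snps_per_chromosome=40, seed=11)
    geno, ped = mg.simulate_population(cfg)
    pheno, truth = mg.simulate_phenotypes(geno, ped, cfg)
    return cfg, geno, ped, pheno, truth


@pytest.fixture(scope="session")
def daughter_genotypes(small_population):
    """Genotype matrix restricted to the genotyped daughters."""
    _, geno, ped, _, _ = small_population
    ids = [a for a in mg.genotyped_ids(ped) if a.startswith("C")]
    return geno.subset(individuals=ids)


def random_genotype_matrix(rng, n_ind=20, n_snps=15, missing_rate=0.1,
                           n_chrom=2):
    d = rng.integers(0, 3, size=(n_ind, n_snps)).astype(float)
    if missing_rate > 0:
        d[rng.random(d.shape) < missing_rate] = np.nan
    per = n_snps // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1),
                      [per] * (n_chrom - 1) + [n_snps - per * (n_chrom - 1)])
    snp_map = pd.DataFrame({
        "snp": [f"s{j}" for j in range(n_snps)],
        "chrom": chrom,
        "pos": np.concatenate([np.sort(rng.choice(10 ** 6, size=c, replace=False))
                               for c in np.bincount(chrom)[1:]]),
        "a1": "A", "a2": "B",
    })
    ids = [f"i{k}" for k in range(n_ind)]
    return mg.GenotypeMatrix(d, ids, snp_map)
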