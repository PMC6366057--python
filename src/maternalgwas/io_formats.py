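"""Readers, writers and validated containers for the pipeline's external formats.

Genotypes travel as PLINK 1 binary triples (BED/BIM/FAM); pedigree and
phenotype tables as delimited text with a header; gene locations as a
TSV. All containers validate their invariants on construction, so a
successfully built object can be trusted downstream.

Dosage convention: a dosage counts copies of the BIM A1 allele
(``allele_alt`` here), so BED code ``00`` (homozygous A1) decodes to 2,
``10`` (het) to 1, ``11`` (homozygous A2) to 0 and ``01`` to missing
(stored as NaN in a float matrix).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

N_AUTOSOMES = 29
FOUNDER = "0"

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01
# 2-bit code -> dosage of A1; NaN encodes the missing code 0b01
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Mutually dependent files disagree (e.g. FAM rows vs BED rows)."""


class ValidationError(ValueError):
    """A container invariant is violated."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with a sorted SNP map.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` float array with values in
        {0, 1, 2, NaN}.
    individual_ids
        Unique, whitespace-free individual identifiers.
    snp_map
        One row per SNP with columns ``snp`` (unique id), ``chrom``
        (autosome 1-29), ``pos`` (1-based bp), ``a1``/``a2`` (counted
        and alternative allele). Must be sorted by (chrom, pos).
    """

    dosages: np.ndarray
    individual_ids: list[str]
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.individual_ids = [str(i) for i in self.individual_ids]
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be a 2-D matrix")
        n_ind, n_snp = self.dosages.shape
        if len(self.individual_ids) != n_ind:
            raise ValidationError(
                f"{len(self.individual_ids)} ids for {n_ind} dosage rows")
        if len(set(self.individual_ids)) != n_ind:
            raise ValidationError("individual ids are not unique")
        sm = self.snp_map.reset_index(drop=True)
        required = {"snp", "chrom", "pos", "a1", "a2"}
        if not required.issubset(sm.columns):
            raise ValidationError(f"snp_map needs columns {sorted(required)}")
        if len(sm) != n_snp:
            raise ValidationError(f"{len(sm)} map rows for {n_snp} SNP columns")
        if sm["snp"].duplicated().any():
            raise ValidationError("SNP ids are not unique")
        chrom = sm["chrom"].to_numpy()
        if len(sm) and ((chrom < 1) | (chrom > N_AUTOSOMES)).any():
            bad = sorted(set(chrom[(chrom < 1) | (chrom > N_AUTOSOMES)]))
            raise ValidationError(f"non-autosomal chromosome(s): {bad}")
        if len(sm) and (sm["pos"].to_numpy() < 1).any():
            raise ValidationError("positions must be 1-based (>= 1)")
        order = np.lexsort((sm["pos"].to_numpy(), chrom))
        if not np.array_equal(order, np.arange(len(sm))):
            raise ValidationError("snp_map must be sorted by (chrom, pos)")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0, 1, 2, NaN}")
        self.snp_map = sm

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual ids / SNP ids."""
        ind_idx = np.arange(self.n_individuals)
        if individuals is not None:
            lookup = {a: i for i, a in enumerate(self.individual_ids)}
            ind_idx = np.array([lookup[a] for a in individuals], dtype=int)
        snp_idx = np.arange(self.n_snps)
        if snps is not None:
            snps = set(snps)
            snp_idx = np.array(
                [j for j, s in enumerate(self.snp_map["snp"]) if s in snps],
                dtype=int)
        return GenotypeMatrix(
            self.dosages[np.ix_(ind_idx, snp_idx)].copy(),
            [self.individual_ids[i] for i in ind_idx],
            self.snp_map.iloc[snp_idx].reset_index(drop=True),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Observed A1 allele frequency per SNP (missing ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclasses.dataclass
class Pedigree:
    """Animal/sire/dam/birth-year records; parent id "0" marks a founder."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        required = {"animal", "sire", "dam", "birth_year"}
        if not required.issubset(df.columns):
            raise ValidationError(f"pedigree needs columns {sorted(required)}")
        for c in ("animal", "sire", "dam"):
            df[c] = df[c].astype(str)
        df.loc[df["sire"].isin(("", "nan", "NA")), "sire"] = FOUNDER
        df.loc[df["dam"].isin(("", "nan", "NA")), "dam"] = FOUNDER
        if df["animal"].duplicated().any():
            dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
            raise ValidationError(f"duplicate pedigree entry for animal {dup}")
        self.records = df
        self._order = self._toposort()

    def _toposort(self) -> list[str]:
        """Parents-before-offspring order; raises naming a cycle member."""
        parents = {
            r.animal: [p for p in (r.sire, r.dam) if p != FOUNDER]
            for r in self.records.itertuples()
        }
        order: list[str] = []
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        for root in parents:
            stack = [(root, iter(parents.get(root, ())))]
            if state.get(root):
                continue
            state[root] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    s = state.get(p)
                    if s == 1:
                        raise ValidationError(
                            f"pedigree cycle involving animal {p}")
                    if s is None and p in parents:
                        state[p] = 1
                        stack.append((p, iter(parents[p])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    order.append(node)
                    stack.pop()
        return order

    @property
    def animals(self) -> list[str]:
        """All animals, parents before offspring."""
        return list(self._order)

    def parents_of(self, animal: str) -> tuple[str, str]:
        row = self.records.loc[self.records["animal"] == animal]
        if row.empty:
            return FOUNDER, FOUNDER
        return row["sire"].iloc[0], row["dam"].iloc[0]


@dataclasses.dataclass
class PhenotypeTable:
    """One weight record per (animal, trait) with Model-style fixed effects.

    ``covariate`` is gestation length in days for birth weight (BW0) and
    age in days for the later weighings (BW23, BW1314).
    """

    records: pd.DataFrame

    TRAITS = ("BW0", "BW23", "BW1314")

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        required = {"animal", "trait", "weight_kg", "herd", "birth_year",
                    "birth_month", "covariate"}
        if not required.issubset(df.columns):
            raise ValidationError(f"phenotypes need columns {sorted(required)}")
        df["animal"] = df["animal"].astype(str)
        bad = set(df["trait"]) - set(self.TRAITS)
        if bad:
            raise ValidationError(f"unknown trait(s): {sorted(bad)}")
        if df.duplicated(subset=["animal", "trait"]).any():
            r = df[df.duplicated(subset=["animal", "trait"])].iloc[0]
            raise ValidationError(
                f"duplicate phenotype for ({r['animal']}, {r['trait']})")
        if len(df) and (df["weight_kg"].to_numpy(float) <= 0).any():
            raise ValidationError("weights must be positive")
        if df["covariate"].isna().any():
            raise ValidationError("covariate missing on some records")
        self.records = df

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.records[self.records["trait"] == trait].reset_index(drop=True)


@dataclasses.dataclass
class GeneTable:
    """Gene intervals: gene_id, chrom (1-29), start_bp <= end_bp (1-based)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.reset_index(drop=True).copy()
        required = {"gene_id", "chrom", "start_bp", "end_bp"}
        if not required.issubset(df.columns):
            raise ValidationError(f"gene table needs columns {sorted(required)}")
        if len(df):
            if (df["start_bp"] > df["end_bp"]).any():
                g = df.loc[df["start_bp"] > df["end_bp"], "gene_id"].iloc[0]
                raise ValidationError(f"gene {g} has start > end")
            c = df["chrom"].to_numpy()
            if ((c < 1) | (c > N_AUTOSOMES)).any():
                raise ValidationError("gene chromosome outside 1-29")
        self.records = df


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def read_plink(prefix_or_bed, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 BED/BIM/FAM triple into a :class:`GenotypeMatrix`.

    Accepts either a path prefix or the three explicit file paths.
    """
    if bim_path is None and fam_path is None:
        prefix = str(prefix_or_bed)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        bed_path = prefix + ".bed"
        bim_path = prefix + ".bim"
        fam_path = prefix + ".fam"
    else:
        bed_path = str(prefix_or_bed)

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    if fam.empty or fam.shape[1] < 2:
        raise ConsistencyError(f"empty or malformed FAM file: {fam_path}")
    ids = fam.iloc[:, 1].tolist()

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise FormatError(f"BIM file needs 6 columns: {bim_path}")
    snp_map = pd.DataFrame({
        "snp": bim.iloc[:, 1],
        "chrom": bim.iloc[:, 0].astype(int),
        "pos": bim.iloc[:, 3].astype(int),
        "a1": bim.iloc[:, 4],
        "a2": bim.iloc[:, 5],
    })

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"bad BED magic bytes in {bed_path}")
    if len(raw) < 3 or raw[2] != _BED_SNP_MAJOR:
        raise FormatError("only SNP-major BED files are supported")
    n_ind, n_snp = len(ids), len(snp_map)
    bytes_per_snp = (n_ind + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * n_snp:
        raise ConsistencyError(
            f"BED payload is {body.size} bytes; expected "
            f"{bytes_per_snp * n_snp} for {n_ind} individuals x {n_snp} SNPs")
    mat = body.reshape(n_snp, bytes_per_snp)
    # unpack the 4 two-bit codes per byte, lowest bits = first sample
    codes = np.stack(
        [(mat >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(n_snp, -1)[:, :n_ind]
    dosages = _CODE_TO_DOSAGE[codes].T
    return GenotypeMatrix(dosages, ids, snp_map)


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write ``geno`` as a PLINK 1 BED/BIM/FAM triple under ``prefix``."""
    for i in geno.individual_ids:
        if any(ch.isspace() for ch in i):
            raise ValidationError(f"id {i!r} contains whitespace")
    prefix = str(prefix)
    with open(prefix + ".fam", "w") as fh:
        for i in geno.individual_ids:
            fh.write(f"0 {i} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for r in geno.snp_map.itertuples():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\t{r.a1}\t{r.a2}\n")

    n_ind, n_snp = geno.n_individuals, geno.n_snps
    d = geno.dosages
    codes = np.full((n_snp, n_ind), 1, dtype=np.uint8)  # 01 = missing
    dt = d.T
    codes[dt == 2.0] = 0b00
    codes[dt == 1.0] = 0b10
    codes[dt == 0.0] = 0b11
    pad = (-n_ind) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((n_snp, pad), dtype=np.uint8)])
    grouped = codes.reshape(n_snp, -1, 4)
    packed = (grouped[..., 0] | (grouped[..., 1] << 2)
              | (grouped[..., 2] << 4) | (grouped[..., 3] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def _read_delim(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def read_pedigree(path) -> Pedigree:
    df = _read_delim(path)
    df["birth_year"] = df["birth_year"].astype(int)
    return Pedigree(df)


def read_phenotypes(path) -> PhenotypeTable:
    df = _read_delim(path)
    df["weight_kg"] = df["weight_kg"].astype(float)
    df["covariate"] = df["covariate"].astype(float)
    return PhenotypeTable(df)


def read_genes(path) -> GeneTable:
    df = _read_delim(path)
    for c in ("chrom", "start_bp", "end_bp"):
        df[c] = df[c].astype(int)
    return GeneTable(df)


def read_tables(pedigree_path, phenotype_path, gene_path):
    """Read the pedigree, phenotype and gene tables in one call."""
    return (read_pedigree(pedigree_path), read_phenotypes(phenotype_path),
            read_genes(gene_path))


def write_pedigree(ped: Pedigree, path) -> None:
    ped.records.to_csv(path, index=False)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.records.to_csv(path, index=False)


def write_genes(genes: GeneTable, path) -> None:
    genes.records.to_csv(path, sep="\t", index=False)
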