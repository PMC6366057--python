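"""Pedigree and genomic relationship matrices, LOCO/segment variants,
and the PCA + k-means population-stratification analysis.

The genomic matrix follows VanRaden's first method,
``G = M M' / (2 * sum_j p_j (1 - p_j))`` with dosages column-centred by
``2 p_j``. Allele frequencies are computed once on the full analyzed SNP
set and reused for every subset matrix (LOCO, per-chromosome, segments),
so that differences between the full matrix and a leave-one-out matrix
reflect SNP removal only, not recentring.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import KMeans

from .io_formats import GenotypeMatrix, Pedigree, ValidationError

__all__ = [
    "RelationshipMatrix", "SegmentScheme", "build_A", "build_G",
    "make_segment_scheme", "build_loco", "build_chrom_G", "pca",
    "kmeans_clusters", "compare_matrices",
]


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric similarity matrix with provenance."""

    matrix: np.ndarray
    ids: list[str]
    kind: str
    snps_used: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("relationship matrix is not symmetric")
        self.matrix = 0.5 * (self.matrix + self.matrix.T)

    def subset(self, ids) -> "RelationshipMatrix":
        lookup = {a: i for i, a in enumerate(self.ids)}
        idx = np.array([lookup[a] for a in ids], dtype=int)
        return RelationshipMatrix(
            self.matrix[np.ix_(idx, idx)], list(ids), self.kind, self.snps_used)


@dataclasses.dataclass
class SegmentScheme:
    """A contiguous partition of the SNP map into exclusion units.

    ``segments`` maps segment id -> (chromosome, list of SNP ids); the
    segments jointly cover every SNP exactly once.
    """

    name: str
    segments: list[tuple[str, int, list[str]]]

    def validate_partition(self, snp_map: pd.DataFrame) -> None:
        seen: list[str] = []
        for _, _, snps in self.segments:
            seen.extend(snps)
        if sorted(seen) != sorted(snp_map["snp"]):
            raise ValidationError(f"{self.name} segments do not partition the map")


# ---------------------------------------------------------------------------
# pedigree relationship matrix (tabular method)
# ---------------------------------------------------------------------------

def build_A(ped: Pedigree, ids=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders (unknown parents) are taken as unrelated and non-inbred;
    inbreeding of descendants accumulates through ``1 + a(s,d)/2`` on
    the diagonal. ``ids`` optionally subsets the result after the full
    recursion (relationships through excluded ancestors are preserved).
    """
    order = ped.animals
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire_of = dict(zip(ped.records["animal"], ped.records["sire"]))
    dam_of = dict(zip(ped.records["animal"], ped.records["dam"]))
    sires = np.array([pos.get(sire_of.get(a, "0"), -1) for a in order])
    dams = np.array([pos.get(dam_of.get(a, "0"), -1) for a in order])

    # generation depth: founders 0, offspring 1 + max(parent depths);
    # the recursion is then vectorized one generation at a time
    depth = np.zeros(n, dtype=int)
    for i in range(n):          # order already has parents first
        d = 0
        if sires[i] >= 0:
            d = depth[sires[i]] + 1
        if dams[i] >= 0:
            d = max(d, depth[dams[i]] + 1)
        depth[i] = d

    A = np.zeros((n, n))
    done = np.zeros(0, dtype=int)
    for g in range(depth.max() + 1):
        lvl = np.flatnonzero(depth == g)
        s, d = sires[lvl], dams[lvl]
        if done.size:
            cross = np.zeros((done.size, lvl.size))
            has_s, has_d = s >= 0, d >= 0
            cross[:, has_s] += 0.5 * A[np.ix_(done, s[has_s])]
            cross[:, has_d] += 0.5 * A[np.ix_(done, d[has_d])]
            A[np.ix_(done, lvl)] = cross
            A[np.ix_(lvl, done)] = cross.T
        # a_ij (i != j, same generation) = 0.5 (a_{i,s(j)} + a_{i,d(j)}),
        # and a_{i, parent} lives in the cross block just written
        within = np.zeros((lvl.size, lvl.size))
        has_s, has_d = s >= 0, d >= 0
        if done.size:
            Als = A[np.ix_(lvl, done)]
            ds_pos = np.searchsorted(done, s[has_s])
            dd_pos = np.searchsorted(done, d[has_d])
            within[:, has_s] += 0.5 * Als[:, ds_pos]
            within[:, has_d] += 0.5 * Als[:, dd_pos]
        np.fill_diagonal(within, 0.0)
        A[np.ix_(lvl, lvl)] = 0.5 * (within + within.T)
        diag = np.ones(lvl.size)
        both = (s >= 0) & (d >= 0)
        diag[both] += 0.5 * A[s[both], d[both]]
        A[lvl, lvl] = diag
        done = np.sort(np.concatenate([done, lvl]))
    result = RelationshipMatrix(A, order, "A")
    if ids is not None:
        result = result.subset(list(ids))
        result.kind = "A"
    return result


def inbreeding_coefficients(ped: Pedigree) -> pd.Series:
    A = build_A(ped)
    return pd.Series(np.diag(A.matrix) - 1.0, index=A.ids)


def build_A_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse-rule inverse of the numerator relationship matrix.

    Uses Henderson's contributions with Mendelian-sampling variances
    adjusted for parental inbreeding, so it is the exact inverse of
    :func:`build_A` (verified against it in the tests).
    """
    order = ped.animals
    pos = {a: i for i, a in enumerate(order)}
    n = len(order)
    F = inbreeding_coefficients(ped).reindex(order).to_numpy()
    Ainv = np.zeros((n, n))
    rec = ped.records.set_index("animal")
    for a, i in pos.items():
        par = []
        if a in rec.index:
            par = [pos[p] for p in (rec.loc[a, "sire"], rec.loc[a, "dam"])
                   if p in pos]
        if len(par) == 2:
            delta = 0.5 - 0.25 * (F[par[0]] + F[par[1]])
        elif len(par) == 1:
            delta = 0.75 - 0.25 * F[par[0]]
        else:
            delta = 1.0
        alpha = 1.0 / delta
        Ainv[i, i] += alpha
        for p in par:
            Ainv[i, p] -= alpha / 2.0
            Ainv[p, i] -= alpha / 2.0
            for q in par:
                Ainv[p, q] += alpha / 4.0
    return RelationshipMatrix(Ainv, order, "A_inverse")


# ---------------------------------------------------------------------------
# genomic relationship matrices
# ---------------------------------------------------------------------------

def _centered_dosages(geno: GenotypeMatrix, snp_idx: np.ndarray,
                      freqs: np.ndarray) -> np.ndarray:
    """Dosages centred by 2p with missing values mean-imputed to 2p."""
    M = geno.dosages[:, snp_idx].copy()
    centre = 2.0 * freqs[snp_idx]
    nan = np.isnan(M)
    if nan.any():
        M[nan] = np.broadcast_to(centre, M.shape)[nan]
    return M - centre


def build_G(geno: GenotypeMatrix, snp_subset=None, allele_freqs=None,
            kind: str = "G_full") -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Parameters
    ----------
    snp_subset
        SNP ids to use (default: all).
    allele_freqs
        Per-SNP frequencies over the *full* map, used both for centring
        and in the ``2 sum p(1-p)`` denominator. Defaults to observed
        frequencies; pass the full-set frequencies when building subset
        matrices so all matrices share one centring.
    """
    if allele_freqs is None:
        allele_freqs = geno.allele_frequencies()
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    if snp_subset is None:
        snp_idx = np.arange(geno.n_snps)
    else:
        wanted = set(snp_subset)
        snp_idx = np.array(
            [j for j, s in enumerate(geno.snp_map["snp"]) if s in wanted],
            dtype=int)
    if snp_idx.size == 0:
        raise ValidationError("empty SNP subset for G")
    p = allele_freqs[snp_idx]
    usable = (p > 0) & (p < 1)
    if not usable.any():
        raise ValidationError("no polymorphic SNPs in subset")
    snp_idx = snp_idx[usable]
    p = p[usable]
    M = _centered_dosages(geno, snp_idx, allele_freqs)
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (M @ M.T) / denom
    return RelationshipMatrix(G, list(geno.individual_ids), kind,
                              snps_used=snp_idx.size)


def make_segment_scheme(snp_map: pd.DataFrame, name: str) -> SegmentScheme:
    """Partition the SNP map into chromosome segments.

    ``SEG40``: chromosomes with more than 1500 SNPs are split at the
    midpoint SNP into two segments, the rest stay whole. ``SEG441`` /
    ``SEG864``: each chromosome is cut into ``round(n / band_mid)``
    contiguous, as-even-as-possible runs aiming for 90-100 / 47-50 SNPs
    per segment; chromosomes shorter than the band minimum become a
    single segment with a warning.
    """
    bands = {"SEG40": None, "SEG441": (90, 100), "SEG864": (47, 50)}
    if name not in bands:
        raise ValidationError(f"unknown segment scheme {name!r}")
    segments: list[tuple[str, int, list[str]]] = []
    for chrom, grp in snp_map.groupby("chrom", sort=True):
        snps = grp["snp"].tolist()
        n = len(snps)
        if name == "SEG40":
            n_seg = 2 if n > 1500 else 1
        else:
            lo, hi = bands[name]
            mid = (lo + hi) / 2.0
            if n < lo:
                warnings.warn(
                    f"chromosome {chrom} has {n} SNPs, below the "
                    f"{name} band minimum {lo}; kept as one segment")
                n_seg = 1
            else:
                n_seg = max(1, round(n / mid))
        sizes = np.full(n_seg, n // n_seg, dtype=int)
        sizes[: n % n_seg] += 1
        start = 0
        for k, size in enumerate(sizes):
            seg_id = f"chr{chrom}" if n_seg == 1 else f"chr{chrom}_seg{k + 1}"
            segments.append((seg_id, int(chrom), snps[start:start + size]))
            start += size
    scheme = SegmentScheme(name, segments)
    scheme.validate_partition(snp_map)
    return scheme


def build_loco(geno: GenotypeMatrix, exclude, allele_freqs=None,
               label=None) -> RelationshipMatrix:
    """G built from all SNPs except the target chromosome or SNP set.

    ``exclude`` is either a chromosome number or an explicit iterable of
    SNP ids (a segment).
    """
    if np.isscalar(exclude):
        mask = geno.snp_map["chrom"].to_numpy() != int(exclude)
        label = label or f"G_loco(chr{int(exclude)})"
    else:
        excluded = set(exclude)
        mask = ~geno.snp_map["snp"].isin(excluded).to_numpy()
        label = label or "G_loco_seg"
    keep = geno.snp_map.loc[mask, "snp"].tolist()
    if not keep:
        raise ValidationError("LOCO exclusion removes every SNP")
    return build_G(geno, snp_subset=keep, allele_freqs=allele_freqs, kind=label)


def build_chrom_G(geno: GenotypeMatrix, chrom: int,
                  allele_freqs=None) -> RelationshipMatrix:
    """G restricted to the SNPs of one chromosome."""
    keep = geno.snp_map.loc[geno.snp_map["chrom"] == int(chrom), "snp"].tolist()
    if not keep:
        raise ValidationError(f"no SNPs on chromosome {chrom}")
    return build_G(geno, snp_subset=keep, allele_freqs=allele_freqs,
                   kind=f"G_chrom({int(chrom)})")


# ---------------------------------------------------------------------------
# stratification analysis
# ---------------------------------------------------------------------------

def pca(K: RelationshipMatrix, n_pc: int):
    """Principal components of a relationship matrix.

    Returns ``(scores, variance_explained)`` where scores are
    eigenvectors scaled by sqrt(eigenvalue) (descending order). Small
    negative eigenvalues (numerical noise) are floored at zero both for
    the scores and for the variance-explained denominator. The sign of
    each component is fixed so its largest-magnitude loading is
    positive.
    """
    n = len(K.ids)
    if n_pc > n:
        raise ValidationError(f"n_pc={n_pc} exceeds matrix size {n}")
    vals, vecs = linalg.eigh(K.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals_pos = np.clip(vals, 0.0, None)
    for j in range(n):
        i_max = np.argmax(np.abs(vecs[:, j]))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = vecs[:, :n_pc] * np.sqrt(vals_pos[:n_pc])
    total = vals_pos.sum()
    var_explained = (vals_pos[:n_pc] / total) if total > 0 else np.zeros(n_pc)
    return scores, var_explained


def kmeans_clusters(scores: np.ndarray, n_pc_used: int = 10, k: int = 3,
                    seed: int = 0, n_start: int = 25) -> np.ndarray:
    """Lloyd k-means on the first ``n_pc_used`` principal components."""
    X = np.asarray(scores)[:, :n_pc_used]
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds number of individuals {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_start, random_state=seed)
    return km.fit_predict(X)


def compare_matrices(K1: RelationshipMatrix, K2: RelationshipMatrix):
    """Off-diagonal agreement between two similarity matrices.

    Returns ``(correlation, slope)``: the Pearson correlation of the
    strict upper triangles, and the coefficient of regressing K1's
    entries on K2's (with intercept).
    """
    if K1.ids != K2.ids:
        raise ValidationError("matrices are over different individuals")
    n = len(K1.ids)
    if n < 3:
        raise ValidationError("need at least 3 individuals to compare")
    iu = np.triu_indices(n, k=1)
    x = K2.matrix[iu]
    y = K1.matrix[iu]
    r = float(np.corrcoef(x, y)[0, 1])
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    return r, slope
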