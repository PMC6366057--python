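"""Relationship matrices, segmentation, PCA/k-means, matrix comparison."""

import numpy as np
import pandas as pd
import pytest

import maternalgwas as mg
from maternalgwas.io_formats import ValidationError
from maternalgwas.kinship import build_A_inverse, make_segment_scheme


def _ped(rows):
    return mg.Pedigree(pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "birth_year"]))


class TestPedigreeA:
    def test_textbook_relationships(self):
        ped = _ped([("S", "0", "0", 2000), ("D", "0", "0", 2000),
                    ("D2", "0", "0", 2000),
                    ("A", "S", "D", 2005), ("B", "S", "D", 2006),
                    ("C", "S", "D2", 2006)])
        A = mg.build_A(ped)
        i = {a: k for k, a in enumerate(A.ids)}
        assert A.matrix[i["A"], i["S"]] == pytest.approx(0.5)
        assert A.matrix[i["A"], i["B"]] == pytest.approx(0.5)     # full sibs
        assert A.matrix[i["A"], i["C"]] == pytest.approx(0.25)    # half sibs

    def test_inbred_offspring_of_half_sibs(self):
        ped = _ped([("S", "0", "0", 2000), ("D", "0", "0", 2000),
                    ("D2", "0", "0", 2000),
                    ("X", "S", "D", 2005), ("Y", "S", "D2", 2005),
                    ("Z", "X", "Y", 2010)])
        A = mg.build_A(ped)
        i = {a: k for k, a in enumerate(A.ids)}
        assert A.matrix[i["Z"], i["Z"]] == pytest.approx(1.125)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_recursive_oracle_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for k in range(40):
            a = f"x{k}"
            if k < 8:
                rows.append((a, "0", "0", 2000))
            else:
                s = f"x{rng.integers(0, k)}"
                d = f"x{rng.integers(0, k)}"
                if s == d:
                    d = "0"
                rows.append((a, s, d, 2005))
        ped = _ped(rows)
        A = mg.build_A(ped)
        pos = {a: k for k, a in enumerate(A.ids)}
        parents = {r[0]: (r[1], r[2]) for r in rows}

        from functools import lru_cache

        @lru_cache(maxsize=None)
        def a_rec(x, y):
            if x == y:
                s, d = parents.get(x, ("0", "0"))
                f = 0.5 * a_rec(*sorted((s, d))) \
                    if s != "0" and d != "0" else 0.0
                return 1.0 + f
            if pos[x] > pos[y]:
                x, y = y, x
            s, d = parents.get(y, ("0", "0"))
            v = 0.0
            if s != "0":
                v += 0.5 * a_rec(*sorted((x, s)))
            if d != "0":
                v += 0.5 * a_rec(*sorted((x, d)))
            return v

        for x in A.ids:
            for y in A.ids:
                assert A.matrix[pos[x], pos[y]] == pytest.approx(
                    a_rec(*sorted((x, y))), abs=1e-12)

    def test_sparse_rule_inverse_is_exact(self, small_population):
        _, _, ped, _, _ = small_population
        A = mg.build_A(ped)
        Ainv = build_A_inverse(ped)
        assert Ainv.ids == A.ids
        np.testing.assert_allclose(Ainv.matrix @ A.matrix,
                                   np.eye(len(A.ids)), atol=1e-8)

    def test_diagonal_at_least_one(self, small_population):
        _, _, ped, _, _ = small_population
        A = mg.build_A(ped)
        assert (np.diag(A.matrix) >= 1.0 - 1e-12).all()


class TestGenomicG:
    def test_single_snp_hand_value(self):
        sm = pd.DataFrame({"snp": ["s"], "chrom": [1], "pos": [1],
                           "a1": "A", "a2": "B"})
        geno = mg.GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]),
                                 ["a", "b", "c"], sm)
        G = mg.build_G(geno)
        # p = 0.5: centred dosages (-1, 0, 1), denominator 2p(1-p) = 0.5
        expected = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0],
                             [-2.0, 0.0, 2.0]])
        np.testing.assert_allclose(G.matrix, expected, atol=1e-12)

    def test_duplicated_individual_rows_identical(self, daughter_genotypes):
        g = daughter_genotypes
        d = np.vstack([g.dosages, g.dosages[:1]])
        dup = mg.GenotypeMatrix(d, g.individual_ids + ["copy"], g.snp_map)
        G = mg.build_G(dup)
        np.testing.assert_allclose(G.matrix[0], G.matrix[-1], atol=1e-12)
        assert G.matrix[0, -1] == pytest.approx(G.matrix[0, 0])

    def test_unrelated_panel_mean_diagonal_near_one(self):
        rng = np.random.default_rng(1)
        m = 600
        p = rng.uniform(0.1, 0.5, m)
        d = rng.binomial(2, p, size=(300, m)).astype(float)
        sm = pd.DataFrame({"snp": [f"s{j}" for j in range(m)], "chrom": 1,
                           "pos": np.arange(1, m + 1), "a1": "A", "a2": "B"})
        G = mg.build_G(mg.GenotypeMatrix(d, [f"i{k}" for k in range(300)],
                                         sm))
        assert abs(np.mean(np.diag(G.matrix)) - 1.0) < 0.05
        offdiag = G.matrix[np.triu_indices(300, 1)]
        assert abs(offdiag.mean()) < 0.01

    def test_empty_subset_rejected(self, daughter_genotypes):
        with pytest.raises(ValidationError):
            mg.build_G(daughter_genotypes, snp_subset=[])

    def test_psd_up_to_noise(self, daughter_genotypes):
        G = mg.build_G(daughter_genotypes)
        vals = np.linalg.eigvalsh(G.matrix)
        assert vals.min() >= -1e-8 * np.trace(G.matrix)


class TestSegments:
    def _map(self, counts):
        rows = []
        for c, n in enumerate(counts, start=1):
            for j in range(n):
                rows.append((f"s{c}_{j}", c, (j + 1) * 100))
        df = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
        df["a1"], df["a2"] = "A", "B"
        return df

    def test_band_split_190_into_two(self):
        scheme = make_segment_scheme(self._map([190]), "SEG441")
        assert len(scheme.segments) == 2
        assert [len(s[2]) for s in scheme.segments] == [95, 95]

    def test_seg40_small_chromosomes_whole(self):
        scheme = make_segment_scheme(self._map([100] * 5), "SEG40")
        assert len(scheme.segments) == 5

    def test_seg40_large_chromosome_split_at_midpoint(self):
        scheme = make_segment_scheme(self._map([1600, 100]), "SEG40")
        sizes = [len(s[2]) for s in scheme.segments]
        assert sorted(sizes) == [100, 800, 800]

    def test_partition_invariant(self):
        snp_map = self._map([190, 47, 120])
        for name in ("SEG40", "SEG441", "SEG864"):
            scheme = make_segment_scheme(snp_map, name)
            seen = [s for _, _, seg in scheme.segments for s in seg]
            assert sorted(seen) == sorted(snp_map["snp"])

    def test_short_chromosome_warns(self):
        with pytest.warns(UserWarning, match="band minimum"):
            make_segment_scheme(self._map([30]), "SEG441")


class TestLocoMatrices:
    def test_loco_uses_other_chromosome_counts(self, daughter_genotypes):
        g = daughter_genotypes
        per_chrom = g.snp_map["chrom"].value_counts()
        K = mg.build_loco(g, 1)
        assert K.snps_used == per_chrom.drop(1).sum()

    def test_excluded_plus_used_covers_all(self, daughter_genotypes):
        g = daughter_genotypes
        scheme = make_segment_scheme(g.snp_map, "SEG40")
        total = 0
        for seg_id, _, snps in scheme.segments:
            K = mg.build_loco(g, snps)
            assert K.snps_used + len(snps) == g.n_snps
            total += len(snps)
        assert total == g.n_snps

    def test_excluding_everything_rejected(self, daughter_genotypes):
        with pytest.raises(ValidationError):
            mg.build_loco(daughter_genotypes,
                          daughter_genotypes.snp_map["snp"].tolist())

    def test_chrom_G_equals_subset_G(self, daughter_genotypes):
        g = daughter_genotypes
        freqs = g.allele_frequencies()
        Gc = mg.build_chrom_G(g, 2, allele_freqs=freqs)
        snps = g.snp_map.loc[g.snp_map["chrom"] == 2, "snp"].tolist()
        Gs = mg.build_G(g, snp_subset=snps, allele_freqs=freqs)
        np.testing.assert_allclose(Gc.matrix, Gs.matrix, atol=1e-12)

    def test_single_chromosome_genome_chrom_equals_full(self):
        cfg = mg.SimConfig(n_sires=2, daughters_per_sire=[15, 15],
                           n_chromosomes=1, snps_per_chromosome=30, seed=2)
        geno, _ = mg.simulate_population(cfg)
        np.testing.assert_allclose(mg.build_chrom_G(geno, 1).matrix,
                                   mg.build_G(geno).matrix, atol=1e-12)


class TestPca:
    def test_identity_matrix_uniform_variance(self):
        K = mg.RelationshipMatrix(np.eye(6), [f"i{k}" for k in range(6)],
                                  "test")
        scores, var_exp = mg.pca(K, 6)
        np.testing.assert_allclose(var_exp, np.full(6, 1 / 6), atol=1e-12)
        assert var_exp.sum() == pytest.approx(1.0)

    def test_two_block_matrix_pc1_separates(self):
        B = np.full((4, 4), 0.5) + 0.5 * np.eye(4)
        K = np.block([[B, np.zeros((4, 4))], [np.zeros((4, 4)), B]])
        scores, _ = mg.pca(mg.RelationshipMatrix(
            K, [f"i{k}" for k in range(8)], "test"), 2)
        signs = np.sign(scores[:, 0])
        assert len(set(signs[:4])) == 1 and len(set(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_n_pc_exceeding_n_rejected(self):
        K = mg.RelationshipMatrix(np.eye(3), ["a", "b", "c"], "t")
        with pytest.raises(ValidationError):
            mg.pca(K, 4)

    def test_sign_convention_deterministic(self, daughter_genotypes):
        G = mg.build_G(daughter_genotypes)
        s1, _ = mg.pca(G, 5)
        s2, _ = mg.pca(G, 5)
        np.testing.assert_array_equal(s1, s2)
        for j in range(5):
            assert s1[np.argmax(np.abs(s1[:, j])), j] >= 0


class TestKmeans:
    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + rng.normal(0, 0.5, (30, 2)) for c in centers])
        labels = mg.kmeans_clusters(X, n_pc_used=2, k=3, seed=1)
        sizes = sorted(np.bincount(labels))
        assert sizes == [30, 30, 30]

    def test_k_one_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        labels = mg.kmeans_clusters(X, n_pc_used=3, k=1, seed=0)
        assert set(labels) == {0}

    def test_same_seed_same_assignment(self):
        X = np.random.default_rng(1).normal(size=(40, 5))
        a = mg.kmeans_clusters(X, n_pc_used=5, k=3, seed=9)
        b = mg.kmeans_clusters(X, n_pc_used=5, k=3, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValidationError):
            mg.kmeans_clusters(np.zeros((2, 2)), k=3, seed=0)


class TestCompareMatrices:
    def test_identical_matrices(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(6, 6))
        K = mg.RelationshipMatrix(M @ M.T, [f"i{k}" for k in range(6)], "t")
        r, slope = mg.compare_matrices(K, K)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_scaled_matrix_closed_form_slope(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(8, 8))
        S = M @ M.T
        iu = np.triu_indices(8, 1)
        S[iu] -= S[iu].mean()          # zero-mean off-diagonals
        S.T[iu] = S[iu]
        ids = [f"i{k}" for k in range(8)]
        K1 = mg.RelationshipMatrix(S, ids, "t")
        K2 = mg.RelationshipMatrix(0.9 * S, ids, "t")
        _, slope = mg.compare_matrices(K1, K2)
        assert slope == pytest.approx(1 / 0.9)

    def test_too_few_individuals_rejected(self):
        K = mg.RelationshipMatrix(np.eye(2), ["a", "b"], "t")
        with pytest.raises(ValidationError):
            mg.compare_matrices(K, K)

    def test_half_sib_pairs_match_pedigree_expectation(self):
        cfg = mg.SimConfig(n_sires=20, daughters_per_sire=[8] * 20,
                           n_chromosomes=5, snps_per_chromosome=100,
                           offspring_per_dam=1, dams_per_grandsire=2,
                           seed=6)
        geno, ped = mg.simulate_population(cfg)
        daughters = [a for a in geno.individual_ids if a.startswith("C")]
        G = mg.build_G(geno).subset(daughters)
        sire_of = dict(zip(ped.records["animal"], ped.records["sire"]))
        fam = np.array([sire_of[a] for a in daughters])
        same = (fam[:, None] == fam[None, :])
        iu = np.triu_indices(len(daughters), 1)
        within = G.matrix[iu][same[iu]]
        assert abs(within.mean() - 0.25) < 0.05
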