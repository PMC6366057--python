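"""REML engines against grid-search, closed-form and library oracles."""

import numpy as np
import pandas as pd
import pytest

import maternalgwas as mg
from maternalgwas.io_formats import ValidationError
from maternalgwas.reml import (RandomTerm, fit_reml, fit_single_kernel_reml,
                               gls_fixed_effects)


def _grid_search_restricted_loglik(y, X, B, n_grid=400):
    """Independent 1-D oracle: maximize the restricted likelihood of
    V = s_u B + s_e I over the variance ratio by explicit-inverse grid
    evaluation, refined twice around the best point."""
    n, p = X.shape

    def restricted(h):
        V = h * B + (1 - h) * np.eye(n)
        Vi = np.linalg.inv(V)
        C = X.T @ Vi @ X
        alpha = np.linalg.solve(C, X.T @ Vi @ y)
        yPy = y @ Vi @ y - (X.T @ Vi @ y) @ alpha
        sp = yPy / (n - p)
        ll = -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(C)[1]
                     + (n - p) * np.log(sp) + (n - p))
        return ll, h * sp, (1 - h) * sp

    lo, hi = 1e-6, 1 - 1e-6
    best = (-np.inf, None, None)
    for _ in range(3):
        grid = np.linspace(lo, hi, n_grid)
        vals = [restricted(h) for h in grid]
        i = int(np.argmax([v[0] for v in vals]))
        best = vals[i]
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_grid - 1)]
    return best


class TestCoreEngines:
    def _grouped_data(self, seed=0, n_groups=40, per=6, s_u=2.0, s_e=1.0):
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(n_groups), per)
        u = rng.normal(0, np.sqrt(s_u), n_groups)
        y = 5.0 + u[g] + rng.normal(0, np.sqrt(s_e), g.size)
        Z = np.zeros((g.size, n_groups))
        Z[np.arange(g.size), g] = 1.0
        B = Z @ Z.T
        X = np.ones((g.size, 1))
        return y, X, B

    def test_generic_engine_matches_grid_oracle(self):
        y, X, B = self._grouped_data()
        _, su_or, se_or = _grid_search_restricted_loglik(y, X, B)
        vc = fit_reml(y, X, [RandomTerm("u", B)])
        assert vc.estimates["u"] == pytest.approx(su_or, abs=1e-3)
        assert vc.estimates["residual"] == pytest.approx(se_or, abs=1e-3)

    def test_eigen_engine_matches_grid_oracle(self):
        y, X, B = self._grouped_data(seed=1)
        _, su_or, se_or = _grid_search_restricted_loglik(y, X, B)
        skf = fit_single_kernel_reml(y, X, B)
        assert skf.sigma_u2 == pytest.approx(su_or, abs=1e-3)
        assert skf.sigma_e2 == pytest.approx(se_or, abs=1e-3)

    def test_two_engines_agree(self):
        y, X, B = self._grouped_data(seed=2)
        vc = fit_reml(y, X, [RandomTerm("u", B)])
        skf = fit_single_kernel_reml(y, X, B)
        assert vc.estimates["u"] == pytest.approx(skf.sigma_u2, rel=1e-3)
        assert vc.estimates["residual"] == pytest.approx(skf.sigma_e2,
                                                         rel=1e-3)

    def test_matches_statsmodels_mixedlm(self):
        """Independent library cross-check on a random-intercept model."""
        import statsmodels.formula.api as smf
        y, X, B = self._grouped_data(seed=3, n_groups=30, per=5)
        groups = np.repeat(np.arange(30), 5)
        df = pd.DataFrame({"y": y, "g": groups})
        sm_fit = smf.mixedlm("y ~ 1", df, groups="g").fit(reml=True)
        vc = fit_reml(y, X, [RandomTerm("u", B)])
        assert vc.estimates["u"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert vc.estimates["residual"] == pytest.approx(
            float(sm_fit.scale), rel=1e-3)

    def test_loglik_non_decreasing(self):
        y, X, B = self._grouped_data(seed=4)
        vc = fit_reml(y, X, [RandomTerm("u", B)])
        diffs = np.diff(vc.trajectory)
        assert (diffs >= -1e-9).all()

    def test_record_and_term_order_invariance(self):
        y, X, B = self._grouped_data(seed=5, n_groups=20, per=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(y.size)
        B2 = 0.5 * np.eye(y.size)
        vc1 = fit_reml(y, X, [RandomTerm("u", B), RandomTerm("v", B2)])
        vc2 = fit_reml(y[perm], X[perm],
                       [RandomTerm("v", B2[np.ix_(perm, perm)]),
                        RandomTerm("u", B[np.ix_(perm, perm)])])
        for k in ("u", "v", "residual"):
            assert vc1.estimates[k] == pytest.approx(vc2.estimates[k],
                                                     rel=1e-4, abs=1e-6)

    def test_zero_noise_degenerate_input(self):
        # grouped signal with no residual noise: sigma_e is driven to
        # its lower bound while the log-likelihood stays monotone
        rng = np.random.default_rng(6)
        n_groups, per = 25, 4
        g = np.repeat(np.arange(n_groups), per)
        u = rng.normal(0, 1.5, n_groups)
        y = 3.0 + u[g]
        Z = np.zeros((g.size, n_groups))
        Z[np.arange(g.size), g] = 1.0
        vc = fit_reml(y, np.ones((g.size, 1)), [RandomTerm("u", Z @ Z.T)])
        assert vc.estimates["residual"] <= 1e-4 * vc.estimates["u"]
        assert (np.diff(vc.trajectory) >= -1e-9).all()

    def test_non_psd_covariance_rejected(self):
        n = 10
        y = np.random.default_rng(7).standard_normal(n)
        bad = -np.eye(n)
        with pytest.raises(ValidationError):
            fit_reml(y, np.ones((n, 1)), [RandomTerm("u", bad)],
                     include_residual=False)


class TestMaternalModel:
    def test_zero_maternal_truth_pinned_and_direct_unbiased(self):
        cfg = mg.SimConfig(n_sires=8, daughters_per_sire=[200] * 8,
                           n_chromosomes=1, snps_per_chromosome=5,
                           var_direct=11.5, var_maternal=0.0,
                           var_mat_pe=0.0, var_residual=13.5, seed=21)
        geno, ped = mg.simulate_population(cfg)
        pheno, _ = mg.simulate_phenotypes(geno, ped, cfg)
        vc, _ = mg.fit_maternal_model(pheno, ped, "BW0")
        sp = cfg.var_direct + cfg.var_residual
        assert vc.ratio("maternal")[0] < 0.08
        assert abs(vc.ratio("direct")[0] - 11.5 / sp) < 0.12

    def test_negative_direct_maternal_covariance_sign_recovered(self):
        cfg = mg.SimConfig(n_sires=8, daughters_per_sire=[250] * 8,
                           n_chromosomes=1, snps_per_chromosome=5,
                           cov_direct_maternal=-4.0, seed=22)
        geno, ped = mg.simulate_population(cfg)
        pheno, _ = mg.simulate_phenotypes(geno, ped, cfg)
        vc, _ = mg.fit_maternal_model(pheno, ped, "BW0",
                                      include_cov_um=True)
        assert vc.estimates["cov_direct_maternal"] < 0

    def test_single_offspring_dams_warn(self):
        cfg = mg.SimConfig(n_sires=2, daughters_per_sire=[30, 30],
                           offspring_per_dam=1, n_chromosomes=1,
                           snps_per_chromosome=5, seed=23)
        geno, ped = mg.simulate_population(cfg)
        pheno, _ = mg.simulate_phenotypes(geno, ped, cfg)
        with pytest.warns(UserWarning, match="weakly identified"):
            mg.fit_maternal_model(pheno, ped, "BW0")


class TestGreml:
    def _greml_data(self, seed, h2, n=500):
        cfg = mg.SimConfig(n_sires=5, daughters_per_sire=[200, 100, 100,
                                                          50, 50],
                           n_chromosomes=5, snps_per_chromosome=60,
                           seed=seed)
        geno, ped = mg.simulate_population(cfg)
        ids = [a for a in mg.genotyped_ids(ped) if a.startswith("C")]
        G = mg.build_G(geno.subset(individuals=ids))
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(G.matrix + 1e-6 * np.eye(len(ids)))
        g = L @ rng.standard_normal(len(ids))
        g = g / g.std()
        y = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.standard_normal(len(ids))
        return pd.Series(y, index=ids), G, g

    def test_genomic_heritability_recovery(self):
        """The genomic heritability (0.33 reported scale) is recovered
        within 2 SE when genetic values are drawn from G."""
        y, G, _ = self._greml_data(31, h2=0.33)
        vc = mg.fit_greml(y, G)
        h2, se = vc.ratio("genomic")
        assert abs(h2 - 0.33) < 2 * max(se, 0.02)

    def test_null_heritability_near_zero(self):
        y, G, _ = self._greml_data(32, h2=0.0)
        vc = mg.fit_greml(y, G)
        assert vc.ratio("genomic")[0] <= 0.05

    def test_identity_kernel_reduces_to_variance_split(self):
        rng = np.random.default_rng(33)
        n = 120
        ids = [f"i{k}" for k in range(n)]
        y = pd.Series(rng.standard_normal(n) * 2 + 1, index=ids)
        G = mg.RelationshipMatrix(np.eye(n), ids, "t")
        vc = mg.fit_greml(y, G)
        # u and e indistinguishable: total variance is preserved
        total = vc.estimates["genomic"] + vc.estimates["residual"]
        assert total == pytest.approx(y.var(ddof=1), rel=0.05)


class TestBivariate:
    def _pair(self, seed, rg_true, h2=0.3):
        cfg = mg.SimConfig(n_sires=5, daughters_per_sire=[200, 100, 100,
                                                          50, 50],
                           n_chromosomes=5, snps_per_chromosome=60,
                           seed=seed)
        geno, ped = mg.simulate_population(cfg)
        ids = [a for a in mg.genotyped_ids(ped) if a.startswith("C")]
        G = mg.build_G(geno.subset(individuals=ids))
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(G.matrix + 1e-6 * np.eye(len(ids)))
        a = L @ rng.standard_normal(len(ids))
        b = L @ rng.standard_normal(len(ids))
        g1 = a / a.std()
        g2 = rg_true * a + np.sqrt(max(1 - rg_true ** 2, 0)) * b
        g2 = g2 / g2.std()
        def trait(g):
            return np.sqrt(h2) * g + np.sqrt(1 - h2) * \
                rng.standard_normal(len(ids))
        return (pd.Series(trait(g1), index=ids),
                pd.Series(trait(g2), index=ids), G)

    def test_identical_traits_unit_correlation(self):
        y1, _, G = self._pair(41, 0.5)
        rg, _ = mg.fit_bivariate_greml(y1, y1, G)
        assert rg == pytest.approx(1.0, abs=1e-3)

    def test_moderate_correlation_recovered(self):
        y1, y2, G = self._pair(42, 0.5)
        rg, se = mg.fit_bivariate_greml(y1, y2, G)
        assert abs(rg - 0.5) < 0.15 + 1e-9 or abs(rg - 0.5) < 2 * se

    def test_independent_genetics_near_zero(self):
        y1, y2, G = self._pair(43, 0.0)
        rg, se = mg.fit_bivariate_greml(y1, y2, G)
        assert abs(rg) < max(0.15, 2 * se)


class TestPrecorrection:
    def test_accounting_identity_exact(self, small_population):
        _, _, ped, pheno, _ = small_population
        _, fit = mg.fit_maternal_model(pheno, ped, "BW0")
        pre = mg.precorrect_phenotypes(fit)
        beta = gls_fixed_effects(fit)
        np.testing.assert_allclose(pre.to_numpy() + fit.X @ beta, fit.y,
                                   atol=1e-8)

    def test_adjusted_tracks_true_random_part(self):
        cfg = mg.SimConfig(n_sires=4, daughters_per_sire=[300, 200, 200,
                                                          100],
                           n_chromosomes=1, snps_per_chromosome=5, seed=44)
        geno, ped = mg.simulate_population(cfg)
        pheno, truth = mg.simulate_phenotypes(geno, ped, cfg)
        _, fit = mg.fit_maternal_model(pheno, ped, "BW0")
        pre = mg.precorrect_phenotypes(fit)
        rand_true = (fit.y - truth.fixed_part.reindex(fit.animal_ids)
                     .to_numpy())
        r = np.corrcoef(pre.to_numpy(), rand_true)[0, 1]
        assert r > 0.95


class TestChromosomePartition:
    def test_planted_chromosome_carries_most_variance(self):
        cfg = mg.SimConfig(n_sires=4, daughters_per_sire=[150, 150, 100,
                                                          100],
                           n_chromosomes=4, snps_per_chromosome=60,
                           n_qtl_direct=15, qtl_chromosomes=(2,),
                           var_direct=12.0, var_maternal=0, var_mat_pe=0,
                           var_residual=8.0, seed=51)
        geno, ped = mg.simulate_population(cfg)
        pheno, _ = mg.simulate_phenotypes(geno, ped, cfg)
        ids = [a for a in mg.genotyped_ids(ped) if a.startswith("C")]
        y = pheno.records.set_index("animal")["weight_kg"]
        part = mg.fit_chromosome_partition(
            pd.Series(y[y.index.isin(ids)]), geno.subset(individuals=ids))
        best = part.table.loc[part.table["var_chrom"].idxmax(), "chrom"]
        assert best == 2
        assert part.table["proportion_of_genomic"].sum() == pytest.approx(1.0)

    def test_null_heritability_partition_small(self):
        cfg = mg.SimConfig(n_sires=4, daughters_per_sire=[100] * 4,
                           n_chromosomes=3, snps_per_chromosome=50,
                           var_direct=0.0, var_maternal=0, var_mat_pe=0,
                           var_residual=20.0, seed=52)
        geno, ped = mg.simulate_population(cfg)
        pheno, _ = mg.simulate_phenotypes(geno, ped, cfg)
        ids = [a for a in mg.genotyped_ids(ped) if a.startswith("C")]
        y = pheno.records.set_index("animal")["weight_kg"]
        part = mg.fit_chromosome_partition(
            pd.Series(y[y.index.isin(ids)]), geno.subset(individuals=ids))
        assert (part.table["h2_chrom"] <= 0.05).all()

    def test_single_chromosome_rejected(self):
        cfg = mg.SimConfig(n_sires=2, daughters_per_sire=[10, 10],
                           n_chromosomes=1, snps_per_chromosome=10, seed=5)
        geno, ped = mg.simulate_population(cfg)
        pheno, _ = mg.simulate_phenotypes(geno, ped, cfg)
        y = pheno.records.set_index("animal")["weight_kg"]
        with pytest.raises(ValidationError):
            mg.fit_chromosome_partition(pd.Series(y), geno)
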