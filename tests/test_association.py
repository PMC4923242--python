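"""Hierarchical regression engine, outlier screening, genetic PCs."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import dmnassoc as da
from dmnassoc._ols import CollinearityError, ols
from dmnassoc.association import (
    build_design,
    interaction_result,
    sex_stratified_refit,
    two_sample_t_from_summary,
)
from dmnassoc.containers import COMPONENTS


class TestOLSEngine:
    def test_matches_normal_equations_oracle(self, rng):
        # brute-force (X'X)^-1 X'y on random small designs
        for _ in range(25):
            n = rng.integers(8, 21)
            p = rng.integers(2, 5)
            X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
            y = rng.standard_normal(n)
            fit = ols(X, y)
            beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(fit.beta, beta_ne, rtol=1e-8)
            rss_ne = float(np.sum((y - X @ beta_ne) ** 2))
            assert fit.rss == pytest.approx(rss_ne, rel=1e-8)

    def test_matches_statsmodels(self, null_cohort):
        geno, cohort, conn = null_cohort
        spec = da.ModelSpec(snp_id="rs7997012", component="R_mPFC")
        X, names, y, _ = build_design(spec, geno, cohort, conn, 3)
        fit = ols(X, y, names)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.beta, ref.params, rtol=1e-10)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.p, ref.pvalues, rtol=1e-8)
        assert fit.df_resid == int(ref.df_resid)

    def test_t_equals_beta_over_se_everywhere(self, null_cohort):
        geno, cohort, conn = null_cohort
        for comp in ("R_mPFC", "L_angular"):
            spec = da.ModelSpec(snp_id="rs130058", component=comp)
            for r in da.fit_block_model(spec, geno, cohort, conn):
                assert r.t_value == pytest.approx(r.beta / r.se, rel=1e-10)

    def test_block_rss_monotone(self, null_cohort):
        geno, cohort, conn = null_cohort
        spec = da.ModelSpec(snp_id="rs6295", component="L_MTG")
        rss = []
        for block in (1, 2, 3):
            X, names, y, _ = build_design(spec, geno, cohort, conn, block)
            rss.append(ols(X, y, names).rss)
        assert rss[0] >= rss[1] >= rss[2]

    def test_exact_noiseless_recovery(self, rng):
        # y = 2 + 3 x + 0 g exactly
        n = 30
        x = rng.standard_normal(n)
        g = rng.integers(0, 3, n).astype(float)
        y = 2 + 3 * x
        fit = ols(np.column_stack([np.ones(n), x, g]), y, ["const", "x", "g"])
        np.testing.assert_allclose(fit.beta, [2.0, 3.0, 0.0], atol=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_phenotype_raises_collinearity(self, null_cohort):
        geno, cohort, conn = null_cohort
        cohort = cohort.copy()
        cohort["severity"] = 5.0
        spec = da.ModelSpec(snp_id="rs6295", component="L_MTG")
        with pytest.raises(CollinearityError, match="severity"):
            da.fit_block_model(spec, geno, cohort, conn)

    def test_genotypic_coding_has_two_df(self, null_cohort):
        geno, cohort, conn = null_cohort
        spec = da.ModelSpec(snp_id="rs6295", component="L_MTG", coding="genotypic")
        res = da.fit_block_model(spec, geno, cohort, conn, blocks=(2,))
        snp_terms = [r for r in res if r.term.startswith("snp[")]
        assert len(snp_terms) == 2


class TestWorkedExample:
    def test_pooled_t_from_group_summaries(self):
        # severe vs mild group contrast recomputed from means/SDs/sizes
        t, p = two_sample_t_from_summary(65.6, 17.3, 65, 18.1, 13.5, 58)
        assert t == pytest.approx(16.837, abs=0.05)
        assert p < 0.001


class TestOutlierScreen:
    def _tables(self, n=135):
        rng = np.random.default_rng(10)
        geno, cohort, conn = da.simulate_cohort(
            da.SimulationConfig(n_subjects=n), rng
        )
        return geno, cohort, conn

    def test_nothing_excluded_when_all_typical(self):
        _, cohort, conn = self._tables()
        retained, excluded = da.screen_outliers(conn, cohort, sd_threshold=6.0)
        assert excluded == []
        assert len(retained) == 135

    def test_joint_outlier_dropped_135_to_134(self):
        _, cohort, conn = self._tables()
        cohort = cohort.copy()
        conn = conn.copy()
        sid = cohort.loc[0, "subject_id"]
        conn.loc[0, "R_MTG"] = conn["R_MTG"].mean() + 8 * conn["R_MTG"].std()
        cohort["blast"] = cohort["blast"].astype(float)
        cohort.loc[0, "blast"] = cohort["blast"].mean() + 8 * cohort["blast"].std()
        retained, excluded = da.screen_outliers(conn, cohort, sd_threshold=3.0)
        assert excluded == [sid]
        assert len(retained) == 134

    def test_connectivity_only_extreme_retained(self):
        _, cohort, conn = self._tables()
        conn = conn.copy()
        conn.loc[0, "R_MTG"] = conn["R_MTG"].mean() + 8 * conn["R_MTG"].std()
        _, excluded = da.screen_outliers(conn, cohort, sd_threshold=3.0)
        assert excluded == []


class TestGeneticPCs:
    def test_identical_subjects_identical_coordinates(self):
        dosage = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 0, 0, 1], [1, 2, 1, 0]])
        geno = da.GenotypeMatrix(dosage, ["a", "b", "c", "d"], ["s1", "s2", "s3", "s4"])
        pcs, _ = da.compute_genetic_pcs(geno, n_pcs=2)
        np.testing.assert_allclose(
            pcs.loc[0, ["pc1", "pc2"]].to_numpy(dtype=float),
            pcs.loc[1, ["pc1", "pc2"]].to_numpy(dtype=float),
            atol=1e-10,
        )

    def test_pcs_orthogonal(self, null_cohort):
        geno, _, _ = null_cohort
        pcs, _ = da.compute_genetic_pcs(geno, n_pcs=3)
        M = pcs[["pc1", "pc2", "pc3"]].to_numpy(dtype=float)
        M = M / np.linalg.norm(M, axis=0)
        off = M.T @ M - np.eye(3)
        assert np.abs(off).max() < 1e-8

    def test_pc1_separates_planted_populations(self):
        # two populations with systematically different MAFs, 100 SNPs
        rng = np.random.default_rng(17)
        n_half, n_snps = 100, 100
        maf_a = rng.uniform(0.1, 0.5, n_snps)
        maf_b = np.clip(maf_a + rng.choice([-0.2, 0.2], n_snps), 0.05, 0.95)
        pop_a = rng.binomial(2, maf_a, (n_half, n_snps))
        pop_b = rng.binomial(2, maf_b, (n_half, n_snps))
        dosage = np.vstack([pop_a, pop_b])
        geno = da.GenotypeMatrix(
            dosage, [f"s{i}" for i in range(2 * n_half)], [f"snp{j}" for j in range(n_snps)]
        )
        pcs, _ = da.compute_genetic_pcs(geno, n_pcs=2)
        pc1 = pcs["pc1"].to_numpy(dtype=float)
        labels = np.r_[np.zeros(n_half), np.ones(n_half)]
        pred = (pc1 > np.median(pc1)).astype(float)
        accuracy = max((pred == labels).mean(), (pred != labels).mean())
        assert accuracy > 0.95

    def test_constant_column_dropped_with_warning(self):
        dosage = np.array([[0, 1, 1], [0, 2, 0], [0, 0, 1], [0, 1, 2]])
        geno = da.GenotypeMatrix(dosage, list("abcd"), ["m1", "m2", "m3"])
        with pytest.warns(UserWarning, match="constant genotype"):
            pcs, flags = da.compute_genetic_pcs(geno, n_pcs=2)
        assert len(flags) == 4


class TestSexStratified:
    def _cohort_with_sex(self, n_female=11):
        rng = np.random.default_rng(23)
        geno, cohort, conn = da.simulate_cohort(da.SimulationConfig(), rng)
        cohort = cohort.copy()
        cohort["sex"] = 0
        cohort.loc[: n_female - 1, "sex"] = 1
        return geno, cohort, conn

    def test_male_stratum_retains_most_subjects(self):
        geno, cohort, conn = self._cohort_with_sex()
        spec = da.ModelSpec(snp_id="rs7997012", component="R_mPFC")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sex_stratified_refit(spec, geno, cohort, conn, stratum=0)
        n_used = res[0].df_resid + 7  # const + 3 covariates + severity + snp + int
        assert n_used >= 120

    def test_female_stratum_runs_and_flags_low_df(self):
        geno, cohort, conn = self._cohort_with_sex(n_female=11)
        spec = da.ModelSpec(snp_id="rs7997012", component="R_mPFC")
        with pytest.warns(UserWarning, match="low residual degrees"):
            res = sex_stratified_refit(spec, geno, cohort, conn, stratum=1)
        assert interaction_result(res).df_resid > 0

    def test_full_stratum_equals_unstratified_without_sex(self):
        geno, cohort, conn = self._cohort_with_sex(n_female=0)
        spec = da.ModelSpec(snp_id="rs7997012", component="R_mPFC")
        with pytest.warns(UserWarning, match="constant covariate"):
            strat = sex_stratified_refit(spec, geno, cohort, conn, stratum=0)
        plain = da.fit_block_model(
            da.ModelSpec(
                snp_id="rs7997012",
                component="R_mPFC",
                covariates=("age", "pc1", "pc2"),
            ),
            geno,
            cohort,
            conn,
        )
        a = interaction_result(strat)
        b = interaction_result(plain)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.t_value == pytest.approx(b.t_value, rel=1e-12)
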