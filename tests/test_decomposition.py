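"""Interaction decomposition: simple effects, stratified ANOVA, confounds."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

import dmnassoc as da
from dmnassoc._ols import CollinearityError, residualize
from dmnassoc.association import interaction_result
from dmnassoc.decomposition import (
    confound_substitution,
    genotype_effect_within_stratum,
    joint_interaction_model,
    partial_correlation,
    simple_effects_by_genotype,
)


class TestPartialCorrelation:
    def test_matches_pingouin(self, rng):
        n = 60
        df = pd.DataFrame(
            rng.standard_normal((n, 4)), columns=["x", "y", "c1", "c2"]
        )
        r, p, dof = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy()
        )
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_equals_residualisation_oracle(self, rng):
        n = 40
        x, y = rng.standard_normal(n), rng.standard_normal(n)
        C = rng.standard_normal((n, 3))
        r, _, _ = partial_correlation(x, y, C)
        Z = np.column_stack([np.ones(n), C])
        rx, ry = residualize(x, Z), residualize(y, Z)
        r_oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert r == pytest.approx(r_oracle, abs=1e-10)


class TestSimpleEffects:
    def test_null_simple_effects_near_zero(self):
        # severity independent of connectivity: per-group r within 3 SE of 0
        cfg = da.SimulationConfig(n_subjects=600)
        geno, cohort, conn = da.simulate_cohort(cfg, np.random.default_rng(8))
        effects = simple_effects_by_genotype(
            "rs6313", "R_MTG", geno, cohort, conn, covariates=()
        )
        for e in effects:
            assert e.defined
            assert abs(e.r) < 3.0 / np.sqrt(e.n)

    def test_negative_interaction_gives_monotone_sign_pattern(self, effect_cohort):
        # injected negative interaction with a positive baseline severity
        # slope: r decreasing in minor-allele count, negative in minor
        # homozygotes, positive in major homozygotes
        _, (geno, cohort, conn) = effect_cohort
        effects = simple_effects_by_genotype("rs6313", "R_MTG", geno, cohort, conn)
        rs = {e.genotype_group: e.r for e in effects if e.defined}
        assert rs[2] < rs[1] < rs[0]
        assert rs[2] < 0 < rs[0]

    def test_group_sizes_sum_to_n(self, null_cohort):
        geno, cohort, conn = null_cohort
        effects = simple_effects_by_genotype("rs6313", "R_MTG", geno, cohort, conn)
        assert sum(e.n for e in effects) == len(cohort)

    def test_small_group_flagged_undefined(self):
        cfg = da.SimulationConfig(
            n_subjects=40, snp_specs=[da.SNPSpec("rare", 0.05, "b1")]
        )
        geno, cohort, conn = da.simulate_cohort(cfg, np.random.default_rng(12))
        effects = simple_effects_by_genotype("rare", "R_MTG", geno, cohort, conn)
        small = [e for e in effects if e.n < 7]
        assert small and all(not e.defined for e in small)
        assert all(np.isnan(e.r) for e in small)


class TestStratifiedAnova:
    def test_equal_group_means_give_f_zero(self, null_cohort):
        geno, cohort, conn = null_cohort
        conn = conn.copy()
        # noiseless fixture: every genotype group gets mean exactly 0.42
        # with nonzero within-group spread
        g = geno.column("rs6313")
        strat = (cohort["diagnosis"] == 1).to_numpy()
        y = conn["R_MTG"].to_numpy().copy()
        for lvl in (0, 1, 2):
            m = strat & (g == lvl)
            vals = np.arange(m.sum(), dtype=float)
            y[m] = 0.42 + (vals - vals.mean())
        conn["R_MTG"] = y
        res = genotype_effect_within_stratum(
            "rs6313", "R_MTG", geno, cohort, conn, "cases"
        )
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_df_bookkeeping(self):
        # a 75-subject stratum with 3 genotype groups has df (2, 72)
        cfg = da.SimulationConfig(n_subjects=160, case_fraction=0.5)
        for seed in range(50):
            geno, cohort, conn = da.simulate_cohort(cfg, np.random.default_rng(seed))
            if (cohort["diagnosis"] == 1).sum() == 75:
                g = geno.column("rs6313")[cohort["diagnosis"] == 1]
                if all((g == lvl).sum() > 0 for lvl in (0, 1, 2)):
                    break
        else:
            pytest.skip("no seed produced a 75-case stratum")
        res = genotype_effect_within_stratum(
            "rs6313", "R_MTG", geno, cohort, conn, "cases"
        )
        assert (res.df1, res.df2) == (2, 72)

    def test_matches_dummy_regression_f(self, null_cohort):
        # classic identity: one-way ANOVA F == F test of the 2-dummy model
        geno, cohort, conn = null_cohort
        res = genotype_effect_within_stratum(
            "rs6313", "R_MTG", geno, cohort, conn, "controls"
        )
        keep = (cohort["diagnosis"] == 0).to_numpy()
        g = geno.column("rs6313")[keep]
        y = conn["R_MTG"].to_numpy()[keep]
        n = len(y)
        X_full = np.column_stack(
            [np.ones(n), (g == 1).astype(float), (g == 2).astype(float)]
        )
        rss_full = float(np.sum(residualize(y, X_full) ** 2))
        rss_red = float(np.sum((y - y.mean()) ** 2))
        F = ((rss_red - rss_full) / 2) / (rss_full / (n - 3))
        assert res.F == pytest.approx(F, rel=1e-10)

    def test_single_group_stratum_rejected(self):
        cfg = da.SimulationConfig(
            n_subjects=12, snp_specs=[da.SNPSpec("mono", 0.02, "b1")]
        )
        geno, cohort, conn = da.simulate_cohort(cfg, np.random.default_rng(1))
        if len(set(geno.dosage[:, 0])) > 1:
            pytest.skip("fixture not monomorphic")
        with pytest.raises(ValueError, match="genotype groups"):
            genotype_effect_within_stratum(
                "mono", "R_MTG", geno, cohort, conn, "cases"
            )


class TestConfoundModels:
    def test_identity_substitution_reproduces_severity_model(self, null_cohort):
        geno, cohort, conn = null_cohort
        cohort = cohort.copy()
        cohort["combat"] = cohort["severity"]  # confound = exact severity copy
        sub = confound_substitution("rs6313", "R_MTG", geno, cohort, conn, "combat")
        base = da.fit_block_model(
            da.ModelSpec(snp_id="rs6313", component="R_MTG"), geno, cohort, conn
        )
        a, b = interaction_result(sub), interaction_result(base)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.p_nominal == pytest.approx(b.p_nominal, rel=1e-12)

    def test_constant_confound_rejected(self, null_cohort):
        geno, cohort, conn = null_cohort
        cohort = cohort.copy()
        cohort["medication"] = 0
        with pytest.raises(ValueError, match="zero variance"):
            confound_substitution("rs6313", "R_MTG", geno, cohort, conn, "medication")

    def test_joint_model_collinearity_error(self, null_cohort):
        geno, cohort, conn = null_cohort
        cohort = cohort.copy()
        cohort["combat"] = 2.0 * cohort["severity"]
        with pytest.raises(CollinearityError):
            joint_interaction_model(
                "rs6313", "R_MTG", geno, cohort, conn, ("severity", "combat")
            )

    def test_joint_model_t_identity(self, null_cohort):
        geno, cohort, conn = null_cohort
        res = joint_interaction_model(
            "rs6313", "R_MTG", geno, cohort, conn, ("severity", "depression")
        )
        for r in res:
            assert r.t_value == pytest.approx(r.beta / r.se, rel=1e-10)

    def test_noise_second_phenotype_leaves_first_estimate(self):
        # adding a pure-noise second moderator leaves the first interaction
        # estimate unchanged on average (within 1 SE)
        diffs, ses = [], []
        for child in np.random.SeedSequence(31).spawn(100):
            rng = np.random.default_rng(child)
            cfg = da.SimulationConfig(
                effect_specs=[da.EffectSpec("rs6313", "R_MTG", 0.0, 0.002)]
            )
            geno, cohort, conn = da.simulate_cohort(cfg, rng)
            cohort = cohort.copy()
            cohort["combat"] = rng.standard_normal(len(cohort))
            single = interaction_result(
                da.fit_block_model(
                    da.ModelSpec(snp_id="rs6313", component="R_MTG"),
                    geno, cohort, conn, blocks=(3,),
                )
            )
            joint = [
                r
                for r in joint_interaction_model(
                    "rs6313", "R_MTG", geno, cohort, conn, ("severity", "combat")
                )
                if r.term.endswith(":severity")
            ][0]
            diffs.append(joint.beta - single.beta)
            ses.append(single.se)
        assert abs(np.mean(diffs)) < np.mean(ses)

    def test_generative_moderator_retained_over_correlated_confound(self):
        # severity drives the interaction; depression only correlates with
        # diagnosis: the joint model keeps the severity term significant
        # more often than the depression term
        sev_hits = dep_hits = 0
        cfg = da.SimulationConfig(
            effect_specs=[da.EffectSpec("rs6313", "R_MTG", 0.0, -0.0025)],
            severity_effects={"R_MTG": 0.0025},
        )
        for child in np.random.SeedSequence(77).spawn(100):
            geno, cohort, conn = da.simulate_cohort(cfg, np.random.default_rng(child))
            if cohort["depression"].nunique() < 2:
                continue
            res = joint_interaction_model(
                "rs6313", "R_MTG", geno, cohort, conn, ("severity", "depression")
            )
            by_term = {r.term: r for r in res}
            if by_term["snp[rs6313]:severity"].p_nominal < 0.05:
                sev_hits += 1
            if by_term["snp[rs6313]:depression"].p_nominal < 0.05:
                dep_hits += 1
        assert sev_hits > dep_hits
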