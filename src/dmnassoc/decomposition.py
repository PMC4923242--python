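"""Post-hoc decomposition of significant SNP x phenotype interactions.

Given an interaction surviving family-wise correction, these routines
dissect it the way an analyst would:

* per-genotype *simple effects*: the partial correlation between severity
  and connectivity within each genotype group, covariates partialled out;
* the genotype effect on connectivity *within diagnosis strata* (one-way
  ANOVA across the three genotype groups in cases and controls separately);
* *confound substitution*: the same hierarchical model with a confound
  (depression, blast, medication, combat exposure) replacing the clinical
  phenotype as the moderator;
* the *joint two-interaction model* entering two moderators' main effects
  and interactions simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import CollinearityError, check_full_rank, ols, residualize
from .association import (
    DEFAULT_COVARIATES,
    AssocResult,
    ModelSpec,
    fit_block_model,
)
from .containers import GenotypeMatrix

CONFOUNDS = ("depression", "blast", "medication", "combat")


@dataclass
class SimpleEffectResult:
    """Severity-connectivity partial correlation within one genotype group."""

    genotype_group: int  # copies of the minor allele
    n: int
    r: float
    p: float
    defined: bool = True


@dataclass
class AnovaResult:
    """One-way genotype ANOVA within a diagnosis stratum."""

    stratum: str
    F: float
    df1: int
    df2: int
    p: float


# ----------------------------------------------------------------------


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariate columns.

    Both variables are residualised on [1, covariates] by OLS and the
    residuals correlated; the two-tailed p uses the t transform on
    ``n - 2 - k`` degrees of freedom for k covariates.
    Returns ``(r, p, df)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = covariates.shape[1] if covariates.size else 0
    Z = np.column_stack([np.ones(n), covariates]) if k else np.ones((n, 1))
    rx = residualize(x, Z)
    ry = residualize(y, Z)
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("zero variance after residualisation")
    r = float((rx @ ry) / denom)
    df = n - 2 - k
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) == 1.0:
        p = 0.0
    else:
        t = r_c * np.sqrt(df / (1.0 - r_c**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, df


def simple_effects_by_genotype(
    snp_id: str,
    component: str,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    phenotype: str = "severity",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[SimpleEffectResult]:
    """Severity-connectivity partial correlation per genotype group.

    Groups with fewer than ``len(covariates) + 3`` subjects are returned
    flagged undefined rather than silently dropped.
    """
    g = geno.column(snp_id)
    pheno = cohort[phenotype].to_numpy(dtype=float)
    y = conn[component].to_numpy(dtype=float)
    C = cohort[list(covariates)].to_numpy(dtype=float)
    out = []
    min_n = len(covariates) + 3
    for group in (0, 1, 2):
        m = g == group
        n = int(m.sum())
        if n < min_n:
            out.append(SimpleEffectResult(group, n, np.nan, np.nan, defined=False))
            continue
        r, p, _ = partial_correlation(pheno[m], y[m], C[m])
        out.append(SimpleEffectResult(group, n, r, p))
    return out


def genotype_effect_within_stratum(
    snp_id: str,
    component: str,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    stratum: str,
    adjust_covariates: tuple[str, ...] | None = None,
) -> AnovaResult:
    """One-way genotype ANOVA on connectivity within cases or controls.

    ``stratum`` is "cases" or "controls" (diagnosis == 1 / 0).  Degrees of
    freedom are ``(groups - 1, n - groups)``.  With ``adjust_covariates``
    the test becomes the ANCOVA partial F for the genotype factor given
    those covariates.
    """
    if stratum not in ("cases", "controls"):
        raise ValueError(f"stratum must be 'cases' or 'controls', got {stratum!r}")
    keep = (cohort["diagnosis"] == (1 if stratum == "cases" else 0)).to_numpy()
    g = geno.column(snp_id)[keep]
    y = conn[component].to_numpy(dtype=float)[keep]
    ok = ~np.isnan(g)
    g, y = g[ok], y[ok]
    groups = [y[g == lvl] for lvl in (0, 1, 2) if (g == lvl).sum() > 0]
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 nonempty genotype groups in {stratum}, found {len(groups)}"
        )
    n = len(y)
    df1 = len(groups) - 1
    df2 = n - len(groups)
    if adjust_covariates:
        Cv = cohort.loc[keep, list(adjust_covariates)].to_numpy(dtype=float)[ok]
        levels = sorted(set(g))
        dummies = np.column_stack([(g == lvl).astype(float) for lvl in levels[1:]])
        X_full = np.column_stack([np.ones(n), Cv, dummies])
        X_red = np.column_stack([np.ones(n), Cv])
        rss_full = float(np.sum(residualize(y, X_full) ** 2))
        rss_red = float(np.sum(residualize(y, X_red) ** 2))
        df2 = n - X_full.shape[1]
        F = ((rss_red - rss_full) / df1) / (rss_full / df2)
        p = float(stats.f.sf(F, df1, df2))
        return AnovaResult(stratum, float(F), df1, df2, p)
    F, p = stats.f_oneway(*groups)
    return AnovaResult(stratum, float(F), df1, df2, float(p))


def confound_substitution(
    snp_id: str,
    component: str,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    confound: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[AssocResult]:
    """Refit the hierarchical model with a confound as the moderator."""
    if confound not in cohort.columns:
        raise ValueError(f"confound {confound!r} not in cohort table")
    if cohort[confound].nunique() <= 1:
        raise ValueError(f"confound {confound!r} has zero variance")
    spec = ModelSpec(
        snp_id=snp_id, component=component, phenotype=confound, covariates=covariates
    )
    return fit_block_model(spec, geno, cohort, conn)


def joint_interaction_model(
    snp_id: str,
    component: str,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    phenotypes: tuple[str, str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[AssocResult]:
    """Single OLS with two moderators' main effects and interactions.

    Model: connectivity ~ covariates + ph1 + ph2 + g + g*ph1 + g*ph2.
    Perfectly collinear phenotypes raise a
    :class:`~dmnassoc._ols.CollinearityError`.
    """
    ph1, ph2 = phenotypes
    g = geno.column(snp_id)
    mask = ~np.isnan(g)
    n = int(mask.sum())
    x1 = cohort[ph1].to_numpy(dtype=float)[mask]
    x2 = cohort[ph2].to_numpy(dtype=float)[mask]
    gv = g[mask]
    y = conn[component].to_numpy(dtype=float)[mask]
    cols = [np.ones(n)]
    names = ["const"]
    for c in covariates:
        cols.append(cohort[c].to_numpy(dtype=float)[mask])
        names.append(c)
    cols += [x1, x2, gv, gv * x1, gv * x2]
    names += [
        ph1,
        ph2,
        f"snp[{snp_id}]",
        f"snp[{snp_id}]:{ph1}",
        f"snp[{snp_id}]:{ph2}",
    ]
    fit = ols(np.column_stack(cols), y, names)
    return [
        AssocResult(
            snp_id=snp_id,
            component=component,
            block=3,
            term=term,
            beta=float(fit.beta[i]),
            se=float(fit.se[i]),
            t_value=float(fit.t[i]),
            p_nominal=float(fit.p[i]),
            df_resid=fit.df_resid,
        )
        for i, term in enumerate(names)
    ]


def simple_effects_to_frame(effects: list[SimpleEffectResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in effects])
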