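"""Hierarchical block regression of DMN connectivity on SNP x phenotype terms.

The engine fits, per (SNP, component) pair, a nested sequence of OLS models:

* **block 1** — connectivity ~ covariates + clinical phenotype,
* **block 2** — block 1 + additive SNP dosage,
* **block 3** — block 2 + SNP x phenotype interaction,

with age, sex and the first two genetic ancestry PCs as default covariates.
Genotype is coded as the count of minor alleles (0/1/2); the interaction is
the raw (uncentred) dosage x phenotype product, so interaction coefficients
are in connectivity units per allele per phenotype unit.  A genotypic
(2-degree-of-freedom dummy) coding and a centred interaction are available
as options for sensitivity analyses.

Also here: the multivariate outlier screen applied before modelling and the
genotype-PCA used to derive ancestry covariates and exclusion flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._ols import CollinearityError, ols
from .containers import COMPONENTS, GenotypeMatrix

DEFAULT_COVARIATES = ("age", "sex", "pc1", "pc2")


@dataclass
class ModelSpec:
    """Specification of one hierarchical (SNP, component) analysis.

    ``phenotype`` is the clinical moderator entered in block 1 and crossed
    with the SNP in block 3 (PTSD severity by default; diagnosis or a
    confound for the substitution analyses).
    """

    snp_id: str
    component: str
    phenotype: str = "severity"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    coding: str = "additive"  # "additive" | "genotypic"
    center_interaction: bool = False

    def __post_init__(self) -> None:
        if self.coding not in ("additive", "genotypic"):
            raise ValueError(f"unknown genotype coding {self.coding!r}")


@dataclass
class AssocResult:
    """One model term from one block of the hierarchical regression."""

    snp_id: str
    component: str
    block: int
    term: str
    beta: float
    se: float
    t_value: float
    p_nominal: float
    df_resid: int


# ----------------------------------------------------------------------
# Summary-statistic utilities


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t test recomputed from printed summaries.

    Used for worked examples checking group contrasts (e.g. case vs
    control severity) against a published descriptive table.  Returns
    ``(t, p)``.
    """
    from scipy import stats as _stats

    res = _stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2)
    return float(res.statistic), float(res.pvalue)


# ----------------------------------------------------------------------
# Screening


def screen_outliers(
    conn: pd.DataFrame,
    cohort: pd.DataFrame,
    sd_threshold: float = 3.0,
    components=COMPONENTS,
) -> tuple[list[str], list[str]]:
    """Multivariate outlier screen on connectivity x blast exposure.

    A subject is excluded only when it lies more than ``sd_threshold``
    sample standard deviations from the mean on at least one DMN component
    *and* on blast exposure (conjunction rule).  Returns
    ``(retained_ids, excluded_ids)``.
    """
    comp = conn[list(components)].to_numpy(dtype=float)
    z_comp = (comp - comp.mean(axis=0)) / comp.std(axis=0, ddof=1)
    blast = cohort["blast"].to_numpy(dtype=float)
    z_blast = (blast - blast.mean()) / blast.std(ddof=1)
    flag = (np.abs(z_comp) > sd_threshold).any(axis=1) & (
        np.abs(z_blast) > sd_threshold
    )
    ids = cohort["subject_id"].tolist()
    excluded = [s for s, f in zip(ids, flag) if f]
    retained = [s for s, f in zip(ids, flag) if not f]
    return retained, excluded


def compute_genetic_pcs(
    geno: GenotypeMatrix, n_pcs: int = 2, outlier_sd: float = 6.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ancestry principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed per SNP; columns are centred at twice
    the allele frequency and scaled by ``sqrt(2 p (1-p))``; constant columns
    are dropped with a warning.  Returns the per-subject PC coordinates and
    a boolean ancestry-outlier flag set when any retained PC coordinate
    exceeds ``outlier_sd`` standard deviations of that PC.
    """
    d = geno.imputed()
    p_hat = d.mean(axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    if not keep.all():
        dropped = [s for s, k in zip(geno.snp_ids, keep) if not k]
        warnings.warn(f"dropping constant genotype columns: {dropped}")
    d = d[:, keep]
    p_hat = p_hat[keep]
    if d.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic SNPs for PCA")
    G = (d - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    U, S, _ = np.linalg.svd(G, full_matrices=False)
    n_pcs = min(n_pcs, S.size)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    sd = pcs.std(axis=0, ddof=1)
    flags = (np.abs(pcs) > outlier_sd * sd).any(axis=1)
    df = pd.DataFrame(pcs, columns=[f"pc{k + 1}" for k in range(n_pcs)])
    df.insert(0, "subject_id", geno.subject_ids)
    return df, flags


# ----------------------------------------------------------------------
# Design construction


def _genotype_columns(
    g: np.ndarray, coding: str, snp_id: str
) -> tuple[np.ndarray, list[str]]:
    if coding == "additive":
        return g[:, None], [f"snp[{snp_id}]"]
    # genotypic: dummies for 1 and 2 copies vs 0
    cols = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
    return cols, [f"snp[{snp_id}==1]", f"snp[{snp_id}==2]"]


def build_design(
    spec: ModelSpec,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    block: int,
):
    """Design matrix, term names, response and subject mask for one block.

    Subjects missing the tested SNP are dropped listwise (blocks 2-3).
    """
    pheno = cohort[spec.phenotype].to_numpy(dtype=float)
    y = conn[spec.component].to_numpy(dtype=float)
    n = len(y)
    mask = np.ones(n, dtype=bool)
    cols = [np.ones(n)]
    names = ["const"]
    for c in spec.covariates:
        cols.append(cohort[c].to_numpy(dtype=float))
        names.append(c)
    cols.append(pheno)
    names.append(spec.phenotype)
    if block >= 2:
        g = geno.column(spec.snp_id)
        mask = ~np.isnan(g)
        gcols, gnames = _genotype_columns(g, spec.coding, spec.snp_id)
        cols.extend(gcols.T)
        names.extend(gnames)
        if block >= 3:
            ph = pheno - pheno[mask].mean() if spec.center_interaction else pheno
            for gc, gn in zip(gcols.T, gnames):
                cols.append(gc * ph)
                names.append(f"{gn}:{spec.phenotype}")
    X = np.column_stack(cols)[mask]
    return X, names, y[mask], mask


def fit_block_model(
    spec: ModelSpec,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    blocks: tuple[int, ...] = (1, 2, 3),
) -> list[AssocResult]:
    """Fit the hierarchical blocks for one (SNP, component) pair.

    Returns one :class:`AssocResult` per term per requested block.  Raises
    :class:`~dmnassoc._ols.CollinearityError` on rank-deficient designs,
    naming the offending terms.
    """
    out: list[AssocResult] = []
    for block in blocks:
        X, names, y, _ = build_design(spec, geno, cohort, conn, block)
        fit = ols(X, y, names)
        for i, term in enumerate(names):
            out.append(
                AssocResult(
                    snp_id=spec.snp_id,
                    component=spec.component,
                    block=block,
                    term=term,
                    beta=float(fit.beta[i]),
                    se=float(fit.se[i]),
                    t_value=float(fit.t[i]),
                    p_nominal=float(fit.p[i]),
                    df_resid=fit.df_resid,
                )
            )
    return out


def interaction_result(results: list[AssocResult]) -> AssocResult:
    """The block-3 interaction term from a :func:`fit_block_model` output."""
    hits = [r for r in results if r.block == 3 and ":" in r.term]
    if not hits:
        raise ValueError("no interaction term in results")
    return hits[0]


def snp_main_result(results: list[AssocResult]) -> AssocResult:
    """The block-2 SNP main-effect term."""
    hits = [r for r in results if r.block == 2 and r.term.startswith("snp[")]
    if not hits:
        raise ValueError("no SNP main-effect term in results")
    return hits[0]


def sex_stratified_refit(
    spec: ModelSpec,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    stratum: int,
    blocks: tuple[int, ...] = (1, 2, 3),
) -> list[AssocResult]:
    """Refit the hierarchical model within one sex stratum.

    ``stratum`` is the value of the binary ``sex`` column to keep.
    Covariates that become constant in the stratum (sex itself, typically)
    are dropped automatically with a warning; a stratum too small to leave
    residual degrees of freedom raises.
    """
    keep = cohort["sex"] == stratum
    if not keep.any():
        raise ValueError(f"empty stratum sex == {stratum}")
    sub_cohort = cohort.loc[keep].reset_index(drop=True)
    sub_conn = conn.loc[keep.to_numpy()].reset_index(drop=True)
    sub_geno = geno.subset(sub_cohort["subject_id"].tolist())
    covs = []
    for c in spec.covariates:
        if sub_cohort[c].nunique() <= 1:
            warnings.warn(f"dropping constant covariate {c!r} in stratum")
        else:
            covs.append(c)
    sub_spec = replace(spec, covariates=tuple(covs))
    results = fit_block_model(sub_spec, sub_geno, sub_cohort, sub_conn, blocks)
    if results and min(r.df_resid for r in results) < 10:
        warnings.warn(
            f"low residual degrees of freedom in stratum sex == {stratum}: "
            f"df={min(r.df_resid for r in results)}"
        )
    return results


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Tabulate results with deterministic (snp, component, block) ordering."""
    df = pd.DataFrame([vars(r) for r in results])
    return df.sort_values(
        ["snp_id", "component", "block"], kind="stable"
    ).reset_index(drop=True)
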