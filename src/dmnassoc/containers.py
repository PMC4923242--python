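"""Core in-memory containers shared across the pipeline.

The pipeline operates on three aligned subject-level tables:

* a :class:`GenotypeMatrix` of additive minor-allele dosages (0/1/2),
* a cohort table (:class:`pandas.DataFrame`) with the clinical phenotype,
  diagnosis, demographic covariates, ancestry PCs and confounds,
* a connectivity table (:class:`pandas.DataFrame`) of Fisher-z seed-to-ROI
  connectivity values, one column per default-mode-network component.

Cohort and connectivity tables are deliberately plain DataFrames (the
idiomatic container for subject-level tabular data); the validators below
enforce the column contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING = -1

#: Canonical ordering of the eight DMN components: seed (posterior
#: cingulate) to isthmus-cingulate, angular gyrus, middle temporal gyrus
#: and medial prefrontal cortex, left/right within each pair.
COMPONENTS = (
    "L_isthmus",
    "R_isthmus",
    "L_angular",
    "R_angular",
    "L_MTG",
    "R_MTG",
    "L_mPFC",
    "R_mPFC",
)

#: Required cohort-table columns (beyond ``subject_id``).
COHORT_COLUMNS = (
    "severity",
    "diagnosis",
    "age",
    "sex",
    "pc1",
    "pc2",
    "depression",
    "blast",
    "medication",
    "combat",
)

_BINARY_COLUMNS = ("diagnosis", "sex", "depression", "medication")


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive minor-allele dosage matrix.

    Parameters
    ----------
    dosage
        Integer array of shape ``(n_subjects, n_snps)`` with entries in
        ``{0, 1, 2}`` (count of minor alleles) or :data:`MISSING`.
    subject_ids, snp_ids
        Row and column labels.
    gene
        Optional gene label per SNP.
    maf
        Per-SNP minor-allele frequency. Recomputed from the dosages when
        omitted; a stored value inconsistent with the dosages (beyond one
        allele count) raises.
    """

    dosage: np.ndarray
    subject_ids: list[str]
    snp_ids: list[str]
    gene: list[str | None] | None = None
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (subjects x SNPs)")
        n, s = self.dosage.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.snp_ids) != s:
            raise ValueError(f"{len(self.snp_ids)} snp ids for {s} columns")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject ids")
        if len(set(self.snp_ids)) != s:
            raise ValueError("duplicate snp ids")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.dosage[~valid])
            raise ValueError(f"dosage entries outside {{0,1,2,{MISSING}}}: {bad}")
        emp = self.empirical_maf()
        if self.maf is None:
            self.maf = emp
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            tol = 1.0 / (2 * n)
            if np.nanmax(np.abs(self.maf - emp)) > tol + 1e-12:
                raise ValueError("stored maf inconsistent with dosages")

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency recomputed from non-missing dosages."""
        d = np.ma.masked_equal(self.dosage, MISSING)
        freq = d.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(freq, dtype=float)

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP (float, missing -> NaN)."""
        j = self.snp_ids.index(snp_id)
        col = self.dosage[:, j].astype(float)
        col[self.dosage[:, j] == MISSING] = np.nan
        return col

    def imputed(self) -> np.ndarray:
        """Float dosage matrix with missing entries mean-imputed per SNP."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        mu = np.nanmean(d, axis=0)
        idx = np.where(np.isnan(d))
        d[idx] = np.take(mu, idx[1])
        return d

    def subset(self, subject_ids: list[str]) -> "GenotypeMatrix":
        """Row-subset (and reorder) by subject id."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [pos[s] for s in subject_ids]
        return GenotypeMatrix(
            self.dosage[rows], list(subject_ids), list(self.snp_ids), self.gene
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosage matrix as a DataFrame with a ``subject_id`` column."""
        df = pd.DataFrame(self.dosage, columns=self.snp_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# ----------------------------------------------------------------------
# Table validators and alignment


def validate_cohort(cohort: pd.DataFrame) -> None:
    missing = [c for c in ("subject_id",) + COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in cohort table: {dup}")
    if (cohort["severity"] < 0).any():
        raise ValueError("severity must be non-negative")
    for col in _BINARY_COLUMNS:
        if not cohort[col].isin((0, 1)).all():
            raise ValueError(f"column {col!r} must be binary 0/1")


def validate_connectivity(conn: pd.DataFrame, components=COMPONENTS) -> None:
    missing = [c for c in ("subject_id",) + tuple(components) if c not in conn.columns]
    if missing:
        raise ValueError(f"connectivity table missing columns: {missing}")
    if conn["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in connectivity table")
    vals = conn[list(components)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite connectivity values")


def align_tables(
    cohort: pd.DataFrame,
    conn: pd.DataFrame,
    geno: GenotypeMatrix | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix | None]:
    """Align all tables row-for-row on ``subject_id``.

    The cohort table's order is canonical; the others are reordered to it
    (with a warning).  Mismatched subject sets raise, listing offenders.
    """
    validate_cohort(cohort)
    ids = cohort["subject_id"].tolist()
    sets = {"connectivity": set(conn["subject_id"])}
    if geno is not None:
        sets["genotype"] = set(geno.subject_ids)
    for name, other in sets.items():
        extra = sorted(other - set(ids))
        lost = sorted(set(ids) - other)
        if extra or lost:
            raise ValueError(
                f"subject-id mismatch with {name} table: "
                f"missing from cohort {extra}, missing from {name} {lost}"
            )
    if conn["subject_id"].tolist() != ids:
        warnings.warn("connectivity table reordered to cohort subject order")
        conn = conn.set_index("subject_id").loc[ids].reset_index()
    if geno is not None and geno.subject_ids != ids:
        warnings.warn("genotype matrix reordered to cohort subject order")
        geno = geno.subset(ids)
    return cohort.reset_index(drop=True), conn.reset_index(drop=True), geno
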