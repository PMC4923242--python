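"""Synthetic veteran-cohort generator.

Generates cohorts with the statistical structure the association analysis
assumes: LD-structured SNP genotypes, correlated Fisher-z connectivity
components, a zero-truncated clinical severity score whose distribution
differs by diagnosis, demographic covariates, confounds, and injectable
SNP main effects and SNP x severity interaction effects.  Also produces
smooth per-subject vertex maps for the cluster module.

The generator's defaults emulate the study population the pipeline was
built around: a predominantly male (91.9%) veteran cohort of 134 analysed
subjects, CAPS-like severity averaging 65.6 (SD 17.3) in current-PTSD
cases and 18.1 (SD 13.5) in controls, a 52.8% case fraction, 7 candidate
serotonin-receptor SNPs with haplotype-block LD, and interaction effects
on the order of 0.002 connectivity units per minor allele per severity
point.

Genotype LD uses a latent-Gaussian threshold model: each haplotype's
alleles derive from a correlated multivariate-normal draw thresholded at
the allele frequency, with the latent correlation solved numerically so
that the realised dosage r-squared matches the configured within-block
target.  Genotypes are Hardy-Weinberg at each SNP's MAF by construction
(two independent haplotypes per subject).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cluster import SurfaceMesh, smooth_noise_maps
from .containers import COMPONENTS, MISSING, GenotypeMatrix

# ----------------------------------------------------------------------
# Reference cohort anchors (the population the defaults emulate)

CASE_SEVERITY = (65.6, 17.3)  # CAPS mean, SD in current-PTSD cases
CONTROL_SEVERITY = (18.1, 13.5)  # CAPS mean, SD in controls
N_CASES, N_CONTROLS = 65, 58  # male case/control split
N_GENOTYPED = 135  # genotyped + imaged, pre outlier screen
N_MALE = 124
N_ANALYSIS = 134  # after the multivariate outlier exclusion
GENOTYPE_SPLIT = {0: 39, 1: 70, 2: 25}  # minor-allele copies at the index SNP
CASE_BLAST = (1.82, 4.1)  # close-range blast count mean, SD
CONTROL_BLAST = (1.00, 3.6)
CASE_COMBAT = (20.4, 12.9)  # combat-exposure score mean, SD
CONTROL_COMBAT = (10.9, 8.6)
CASE_DEPRESSION, CONTROL_DEPRESSION = 0.22, 0.02
CASE_MEDICATION, CONTROL_MEDICATION = 0.28, 0.05
AGE = (31.39, 7.97)
FEMALE_FRACTION = (N_GENOTYPED - N_MALE) / N_GENOTYPED
#: MAF back-derived from the printed genotype-group counts 25/70/39
#: (no MAFs are reported directly): (2*25 + 70) / (2*134).
INDEX_SNP_MAF = (2 * GENOTYPE_SPLIT[2] + GENOTYPE_SPLIT[1]) / (2 * N_ANALYSIS)


@dataclass
class SNPSpec:
    """One simulated SNP: MAF, haplotype block membership, optional gene."""

    snp_id: str
    maf: float
    block_id: str
    gene: str | None = None


@dataclass
class EffectSpec:
    """Injected effect of one SNP on one connectivity component.

    ``beta_main`` is in connectivity units per minor allele;
    ``beta_interaction`` in connectivity units per allele per severity unit.
    """

    snp_id: str
    component: str
    beta_main: float = 0.0
    beta_interaction: float = 0.0


@dataclass
class SignalSpec:
    """Signal patch added to vertex maps.

    The value ``amplitude * subject_weight[i]`` is added at each patch
    vertex of subject i; pass dosage x severity as the weight to plant a
    SNP x severity interaction signal.
    """

    vertices: np.ndarray
    amplitude: float
    subject_weight: np.ndarray | None = None


def _default_snp_specs() -> list[SNPSpec]:
    # Seven candidate serotonin-receptor SNPs; MAFs are plausible common-SNP
    # values, with the HTR2A index SNP pinned to the back-derived 0.448.
    return [
        SNPSpec("rs6295", 0.49, "HTR1A_b1", "HTR1A"),
        SNPSpec("rs6296", 0.28, "HTR1B_b1", "HTR1B"),
        SNPSpec("rs130058", 0.26, "HTR1B_b1", "HTR1B"),
        SNPSpec("rs11568817", 0.33, "HTR1B_b1", "HTR1B"),
        SNPSpec("rs7997012", 0.38, "HTR2A_b1", "HTR2A"),
        SNPSpec("rs6313", 0.44, "HTR2A_b1", "HTR2A"),
        SNPSpec("rs1176744", 0.28, "HTR3B_b1", "HTR3B"),
    ]


@dataclass
class SimulationConfig:
    """Full specification of a simulated cohort.

    Defaults reproduce the reference study conditions; the various effect
    fields default to the global null.
    """

    n_subjects: int = N_ANALYSIS
    snp_specs: list[SNPSpec] = field(default_factory=_default_snp_specs)
    within_block_r2: float = 0.6
    n_components: int = 8
    component_corr: float | np.ndarray = 0.35
    effect_specs: list[EffectSpec] = field(default_factory=list)
    severity_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    severity_case_mean: float = CASE_SEVERITY[0]
    severity_case_sd: float = CASE_SEVERITY[1]
    severity_control_mean: float = CONTROL_SEVERITY[0]
    severity_control_sd: float = CONTROL_SEVERITY[1]
    case_fraction: float = N_CASES / (N_CASES + N_CONTROLS)
    age_mean: float = AGE[0]
    age_sd: float = AGE[1]
    female_fraction: float = FEMALE_FRACTION
    pc_sd: float = 1.0
    baseline: float = 0.3
    noise_sd: float = 0.12
    missing_rate: float = 0.0
    seed: int | None = None

    # ------------------------------------------------------------------
    @property
    def components(self) -> tuple[str, ...]:
        return COMPONENTS[: self.n_components]

    def corr_matrix(self) -> np.ndarray:
        c = self.n_components
        if np.isscalar(self.component_corr):
            rho = float(self.component_corr)
            if not -1 < rho < 1:
                raise ValueError(f"component correlation {rho} outside (-1, 1)")
            R = np.full((c, c), rho)
            np.fill_diagonal(R, 1.0)
        else:
            R = np.asarray(self.component_corr, dtype=float)
            if R.shape != (c, c):
                raise ValueError("component correlation matrix has wrong shape")
            if not np.allclose(R, R.T):
                raise ValueError("component correlation matrix not symmetric")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("component correlation matrix not positive semi-definite")
        return R

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if not self.snp_specs:
            raise ValueError("no SNPs specified")
        for s in self.snp_specs:
            if not 0 < s.maf <= 0.5:
                raise ValueError(
                    f"MAF for {s.snp_id} must be in (0, 0.5], got {s.maf}"
                )
        if len({s.snp_id for s in self.snp_specs}) != len(self.snp_specs):
            raise ValueError("duplicate snp ids in snp_specs")
        if not 0 <= self.within_block_r2 <= 1:
            raise ValueError("within_block_r2 must be in [0, 1]")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0, 1)")
        if not 1 <= self.n_components <= len(COMPONENTS):
            raise ValueError(f"n_components must be in [1, {len(COMPONENTS)}]")
        if self.noise_sd < 0 or self.missing_rate < 0 or self.missing_rate >= 1:
            raise ValueError("noise_sd must be >= 0 and missing_rate in [0, 1)")
        self.corr_matrix()
        snp_ids = {s.snp_id for s in self.snp_specs}
        for e in self.effect_specs:
            if e.snp_id not in snp_ids:
                raise ValueError(f"effect_spec references unknown SNP {e.snp_id!r}")
            if e.component not in self.components:
                raise ValueError(
                    f"effect_spec references unknown component {e.component!r}"
                )
        for comp in self.severity_effects:
            if comp not in self.components:
                raise ValueError(f"severity effect on unknown component {comp!r}")


# ----------------------------------------------------------------------
# Genotypes


def _allele_corr(rho: float, tau_i: float, tau_j: float, p_i: float, p_j: float) -> float:
    """Pearson correlation of thresholded-Gaussian alleles at latent rho."""
    p11 = stats.multivariate_normal.cdf(
        [tau_i, tau_j], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    return (p11 - p_i * p_j) / np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))


def _solve_latent_rho(p_i: float, p_j: float, target_r: float) -> float:
    """Latent correlation yielding a given allele-level phi coefficient."""
    if target_r <= 0:
        return 0.0
    tau_i, tau_j = stats.norm.ppf(p_i), stats.norm.ppf(p_j)
    hi = 0.999999
    top = _allele_corr(hi, tau_i, tau_j, p_i, p_j)
    if top < target_r - 1e-9:
        raise ValueError(
            f"target allele correlation {target_r:.3f} unattainable for MAFs "
            f"{p_i:.3f}/{p_j:.3f} (maximum {top:.3f}); equalise MAFs or lower r2"
        )
    return optimize.brentq(
        lambda r: _allele_corr(r, tau_i, tau_j, p_i, p_j) - target_r,
        0.0,
        hi,
        xtol=1e-10,
    )


def _block_haplotypes(
    mafs: np.ndarray, r2: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Dosages (n, k) for one haplotype block at pairwise dosage r^2 ~ r2."""
    k = len(mafs)
    taus = stats.norm.ppf(mafs)
    if k == 1:
        alleles = rng.random((n, 2)) < mafs[0]
        return alleles.sum(axis=1)[:, None]
    target_r = float(np.sqrt(r2))
    if r2 == 1.0:
        if not np.allclose(mafs, mafs[0]):
            raise ValueError("perfect LD (r2 = 1) requires equal MAFs in the block")
        z = rng.standard_normal((n, 2))
        dos = (z < taus[0]).sum(axis=1)  # identical latent for all SNPs
        return np.repeat(dos[:, None], k, axis=1).astype(np.int64)
    Sigma = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            Sigma[i, j] = Sigma[j, i] = _solve_latent_rho(mafs[i], mafs[j], target_r)
    w, V = np.linalg.eigh(Sigma)
    L = V * np.sqrt(np.clip(w, 1e-12, None))
    z = rng.standard_normal((n, 2, k)) @ L.T
    alleles = z < taus
    return alleles.sum(axis=1).astype(np.int64)


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    """Draw an LD-structured genotype matrix.

    SNPs sharing a ``block_id`` get pairwise dosage r^2 approximately equal
    to ``config.within_block_r2`` via the latent-Gaussian threshold
    construction; SNPs in distinct blocks are independent in expectation;
    every SNP is Hardy-Weinberg at its configured MAF.
    """
    config.validate()
    n = config.n_subjects
    specs = config.snp_specs
    order: dict[str, list[int]] = {}
    for idx, s in enumerate(specs):
        order.setdefault(s.block_id, []).append(idx)
    dosage = np.empty((n, len(specs)), dtype=np.int8)
    for block_idx in order.values():
        mafs = np.array([specs[i].maf for i in block_idx])
        dosage[:, block_idx] = _block_haplotypes(
            mafs, config.within_block_r2, n, rng
        )
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(
        dosage,
        subject_ids,
        [s.snp_id for s in specs],
        gene=[s.gene for s in specs],
    )


# ----------------------------------------------------------------------
# Cohort


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _neg_binomial_counts(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Overdispersed count draws matching a target mean and SD."""
    var = sd**2
    if var <= mean:  # no overdispersion possible; fall back to Poisson
        return rng.poisson(mean, size)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate aligned genotype, cohort and connectivity tables.

    The connectivity model is, per component c:

        y_c = baseline + covariate effects + b_sev(c) * severity
              + sum over effects [ b_main * g + b_int * g * severity ]
              + correlated Gaussian noise (SD ``noise_sd``, correlation
                ``component_corr`` across components).

    Severity is truncated-normal at zero with diagnosis-specific location
    and scale; confounds (depression, blast, medication, combat) follow the
    reference cohort's per-diagnosis distributions.
    """
    config.validate()
    n = config.n_subjects
    geno = simulate_genotypes(config, rng)

    diagnosis = (rng.random(n) < config.case_fraction).astype(int)
    severity = np.where(
        diagnosis == 1,
        _truncated_normal(config.severity_case_mean, config.severity_case_sd, n, rng),
        _truncated_normal(
            config.severity_control_mean, config.severity_control_sd, n, rng
        ),
    )
    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = (rng.random(n) < config.female_fraction).astype(int)  # 1 = female
    pc1 = rng.normal(0.0, config.pc_sd, n)
    pc2 = rng.normal(0.0, config.pc_sd, n)
    depression = np.where(
        diagnosis == 1,
        rng.random(n) < CASE_DEPRESSION,
        rng.random(n) < CONTROL_DEPRESSION,
    ).astype(int)
    blast_case = _neg_binomial_counts(*CASE_BLAST, n, rng)
    blast_ctrl = _neg_binomial_counts(*CONTROL_BLAST, n, rng)
    blast = np.where(diagnosis == 1, blast_case, blast_ctrl)
    medication = np.where(
        diagnosis == 1,
        rng.random(n) < CASE_MEDICATION,
        rng.random(n) < CONTROL_MEDICATION,
    ).astype(int)
    combat_case = _truncated_normal(*CASE_COMBAT, n, rng)
    combat_ctrl = _truncated_normal(*CONTROL_COMBAT, n, rng)
    combat = np.where(diagnosis == 1, combat_case, combat_ctrl)

    cohort = pd.DataFrame(
        dict(
            subject_id=geno.subject_ids,
            severity=severity,
            diagnosis=diagnosis,
            age=age,
            sex=sex,
            pc1=pc1,
            pc2=pc2,
            depression=depression,
            blast=blast,
            medication=medication,
            combat=combat,
        )
    )

    comps = config.components
    mu = np.full((n, len(comps)), config.baseline)
    for j, comp in enumerate(comps):
        mu[:, j] += config.severity_effects.get(comp, 0.0) * severity
    for cov, per_comp in config.covariate_effects.items():
        x = cohort[cov].to_numpy(dtype=float)
        for comp, beta in per_comp.items():
            mu[:, comps.index(comp)] += beta * x
    dos = geno.imputed()
    for e in config.effect_specs:
        g = dos[:, geno.snp_ids.index(e.snp_id)]
        j = comps.index(e.component)
        mu[:, j] += e.beta_main * g + e.beta_interaction * g * severity

    R = config.corr_matrix()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(comps)))
    noise = config.noise_sd * (rng.standard_normal((n, len(comps))) @ L.T)
    conn = pd.DataFrame(mu + noise, columns=list(comps))
    conn.insert(0, "subject_id", geno.subject_ids)
    return geno, cohort, conn


# ----------------------------------------------------------------------
# Vertex maps


def simulate_vertex_maps(
    mesh: SurfaceMesh,
    n_subjects: int,
    smoothing_steps: int,
    signal_spec: SignalSpec | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-subject smooth Gaussian vertex maps with an optional signal patch.

    Returns an (n_subjects, n_vertices) array: iid standard-normal fields
    graph-smoothed ``smoothing_steps`` times, plus
    ``amplitude * subject_weight`` added at the patch vertices.
    """
    maps = smooth_noise_maps(mesh, n_subjects, smoothing_steps, rng)
    if signal_spec is not None:
        verts = np.asarray(signal_spec.vertices, dtype=np.intp)
        if verts.size and (verts.min() < 0 or verts.max() >= mesh.n_vertices):
            raise ValueError("signal patch vertices outside mesh")
        w = (
            np.ones(n_subjects)
            if signal_spec.subject_weight is None
            else np.asarray(signal_spec.subject_weight, dtype=float)
        )
        if w.shape != (n_subjects,):
            raise ValueError("subject_weight must have one value per subject")
        maps[:, verts] += signal_spec.amplitude * w[:, None]
    return maps
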