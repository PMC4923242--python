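# dmnassoc

Imaging-genetics interaction analysis for seed-based resting-state
connectivity: does a SNP moderate the association between a clinical
severity score and default-mode-network (DMN) connectivity?

The package is aimed at analysts working with modest candidate-gene
neuroimaging cohorts (n in the low hundreds), where a handful of SNPs in
linkage disequilibrium are tested against a handful of correlated
connectivity phenotypes and familywise error control must respect both
correlation structures. It was built around a veteran PTSD cohort design
(134 subjects, 8 posterior-cingulate-seeded DMN components, candidate
serotonin-receptor SNPs), and ships a synthetic-cohort generator that
reproduces that design's statistical structure, since the original
subject-level data are not publicly deposited.

## The model

For each SNP *s* (additive minor-allele dosage g ∈ {0,1,2}) and DMN
component *c* (Fisher-z seed connectivity y), a hierarchical OLS sequence
is fitted with covariates **x** = (age, sex, PC1, PC2):

1. block 1: y = α + **β**ᵀ**x** + β_sev · sev
2. block 2: … + β_g · g
3. block 3: … + β_int · (g × sev)

The interaction coefficient β_int (connectivity units per allele per
severity point) is the quantity of interest. Familywise error across all
(SNP, component) pairs is controlled by **max-|t| permutation**: each of B
replicates permutes the subject order of the whole genotype matrix as one
unit (preserving LD between SNPs and the correlations between components),
refits the family, and records max |t|; then

p_corr(s, c) = (1 + #{b : max|t|_b ≥ |t|_obs(s, c)}) / (B + 1).

Significant interactions are decomposed into per-genotype partial
correlations, within-diagnosis genotype ANOVAs, confound-substitution
models, and a joint two-interaction model. A vertex-wise analogue runs the
same GLM at every vertex of a mesh and assigns cluster-wise p-values from
the Monte-Carlo null distribution of the maximum cluster extent.

## Worked example

```python
import numpy as np
import dmnassoc as da

cfg = da.SimulationConfig(
    effect_specs=[da.EffectSpec("rs6313", "R_MTG", beta_interaction=-0.0025)],
    severity_effects={"R_MTG": 0.0025},
)
geno, cohort, conn = da.simulate_cohort(cfg, np.random.default_rng(21))

res = da.maxt_correct(
    geno, cohort, conn, da.PermutationConfig(n_replicates=10_000, seed=1)
)
print(res.table.sort_values("p_corrected").head(3).to_string(index=False))

for e in da.simple_effects_by_genotype("rs6313", "R_MTG", geno, cohort, conn):
    print(f"{e.genotype_group} copies: n={e.n:3d}  r={e.r:+.3f}  p={e.p:.3f}")
```

prints

```
   snp_id component        term   t_value  p_nominal  p_corrected
   rs6313     R_MTG interaction -4.711838   0.000006     0.000600
rs7997012     R_MTG interaction -4.199030   0.000050     0.003900
   rs6313 L_angular interaction  2.357540   0.019937     0.531847

0 copies: n= 41  r=+0.620  p=0.000
1 copies: n= 67  r=-0.008  p=0.948
2 copies: n= 26  r=-0.698  p=0.000
```

The injected negative interaction on the PCC–right-MTG component survives
joint correction across the 7 SNPs × 8 components (p_corr = 6×10⁻⁴), as
does its echo at rs7997012, which sits in the same haplotype block as
rs6313 (within-block r² = 0.6 by default) — exactly the LD-induced
co-signal the joint permutation is designed to price in. The per-genotype
simple effects show the expected monotone pattern: the
severity–connectivity correlation is positive in major-allele
homozygotes, near zero in heterozygotes, and negative in minor-allele
homozygotes.

The same analyses are available from the shell via the `dmnassoc` CLI
(`simulate`, `connectivity`, `assoc`, `correct`, `run-all`, `decompose`,
`cluster`, `calibrate`); every command takes an explicit `--seed` and
writes a provenance file next to its outputs.

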