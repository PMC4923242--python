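# Methods

## Scope and data model

`dmnassoc` analyses three aligned subject-level tables: additive
minor-allele dosages (0/1/2 with a missing sentinel), a clinical/covariate
table (severity score, binary diagnosis, age, sex, two genetic ancestry
PCs, and the confounds depression, blast-exposure count, antidepressant
use, combat-exposure score), and a connectivity table of eight Fisher-z
posterior-cingulate-seeded DMN components (left/right isthmus cingulate,
angular gyrus, middle temporal gyrus, medial prefrontal cortex — this
ordering is canonical project-wide). Everything upstream of ROI-mean time
series (surface reconstruction, registration, smoothing, nuisance
regression) is out of scope.

## Hierarchical interaction regression

Per (SNP, component) pair, three nested OLS models are fitted:
covariates + severity (block 1), + dosage (block 2), + dosage × severity
(block 3). Choices a user should know about:

* **Genotype coding** is additive minor-allele dosage; a genotypic
  (two-dummy) coding is available via `ModelSpec(coding="genotypic")` for
  sensitivity analyses.
* **The interaction uses the raw (uncentred) product.** Interaction
  coefficients are then in connectivity units per allele per severity
  point, the scale on which effect sizes around 0.002 are meaningful for
  CAPS-like severity (range ~0–120). `center_interaction=True` switches to
  the centred product, which changes the main-effect terms but not the
  interaction t.
* **Missing genotypes** drop the subject listwise for that SNP's models.
* Two-tailed t tests on residual df = n − p; rank-deficient designs raise
  a `CollinearityError` naming the offending term (identified as the first
  column adding no rank over those entered before it).
* The outlier screen is a conjunction rule: exclusion requires > k SD from
  the sample mean on at least one DMN component *and* on blast exposure
  (default k = 3). Ancestry PCs come from the SVD of the
  (2p, √(2p(1−p)))-standardised dosage matrix, with mean imputation of
  missing calls and a 6-SD ancestry-outlier flag.

## Joint-permutation FWER correction

The family is all tested (SNP, component) pairs for one term (interaction
or SNP main effect). Each replicate permutes the subject order of the
entire genotype matrix as one unit — phenotype, covariates, and
connectivity stay put — so every replicate preserves both the LD between
SNPs and the correlation between components, which is what lets the
correction beat Bonferroni on correlated families. The corrected p is the
add-one exceedance probability of the family-wide max |t|, so its floor is
1/(B+1) and it never returns zero. B defaults to 10,000.

Two properties are documented rather than "fixed": (i) permuting raw
genotypes tests the *full* null of no SNP main effect and no interaction
(a Freedman–Lane residual permutation is a noted, unimplemented
alternative); (ii) the permutation refits use the Frisch–Waugh–Lovell
partialling identity (residualise the tested columns and the responses on
the fixed block, then solve the remaining 1- or 2-column system in closed
form, batched over permutations). This is algebraically identical to
refitting the full model — the test suite verifies equality against the
scalar engine at 1e-15 — and is what makes 10,000-replicate runs on a
7 × 8 family take seconds rather than hours. For n ≤ 8 subjects the
correction can enumerate all n! permutations exactly
(`maxt_correct(..., exhaustive=True)`); the exact p is then a plain
proportion over the full group, identity included. Missing genotypes are
mean-imputed (with a warning) inside the permutation engine, since
per-SNP listwise deletion is incompatible with permuting rows jointly.

## Decomposition

Simple effects are partial correlations of severity and connectivity
within each genotype group, covariates partialled out by OLS
residualisation, with p from the t transform on df = n − 2 − k; groups
smaller than k + 3 are returned flagged undefined. The within-diagnosis
genotype test is a plain one-way ANOVA with df (groups − 1, n − groups) —
unadjusted, because that is the df convention the decomposition targets —
with an ANCOVA partial-F variant behind `adjust_covariates`. Confound
substitution swaps the moderator and refits the identical block
structure; the joint model enters both moderators' main effects and
interactions in one OLS.

## Cluster-extent inference

The vertex-wise GLM is the block-3 model vectorised across mesh vertices.
Suprathreshold vertices (p < vertex_p, default 0.05) are clustered as
connected components of the mesh graph *separately by statistic sign*, so
adjacent opposite-direction effects stay distinct. Cluster size is vertex
count, or summed per-vertex area when the mesh provides one. The null
distribution of the maximum cluster size is simulated by drawing smooth
Gaussian noise maps for the same subjects and design and re-running the
identical GLM + threshold + clustering; cluster-wise p uses the same
add-one estimator. Smoothness is parameterised as the number of
nearest-neighbour graph-smoothing steps (each step replaces a vertex by
the mean of itself and its neighbours) rather than a FWHM estimated from
residuals — faithful to the Monte-Carlo logic without surface-geometry
machinery, so the calibration constants are not claimed to match any
specific cortical-surface implementation.

## Synthetic cohort generator

The generator reproduces the statistical structure of the reference
veteran cohort the pipeline was designed around; its defaults *are* the
study conditions and are not tuned per analysis:

* n = 134 subjects; 52.8% current-PTSD cases; 91.9% male; age 31.4 ± 8.0.
* Severity is truncated-normal at zero, 65.6 ± 17.3 in cases and
  18.1 ± 13.5 in controls (the published distributional anchors).
  Confounds follow the published per-diagnosis summaries: depression
  0.22/0.02 (the control rate is set to 2% rather than the printed 0% so
  the confound-substitution models remain estimable), medication
  0.28/0.05, blast counts as negative-binomial draws matching the printed
  means/SDs (1.82 ± 4.1 vs 1.00 ± 3.6), combat truncated-normal
  (20.4 ± 12.9 vs 10.9 ± 8.6).
* Seven candidate serotonin-receptor SNPs grouped into haplotype blocks.
  No MAFs are published for the panel; the HTR2A index SNP's 0.448 is
  back-derived from the printed 25/70/39 genotype split and the rest are
  plausible common-SNP values. LD within a block uses a latent-Gaussian
  threshold model: per haplotype, a correlated multivariate-normal draw is
  thresholded at Φ⁻¹(MAF), with the latent correlation solved by Brent's
  method so the allele-level φ equals √r²_target (dosages are sums of two
  iid haplotypes, so dosage r² matches the target). The default
  within-block r² is 0.6, the published LD between the two HTR2A index
  SNPs; r² = 1 requires equal MAFs and reuses one latent variable,
  giving bit-identical columns. Genotypes are Hardy–Weinberg by
  construction. Unattainable φ targets (very unequal MAFs) raise with a
  diagnostic rather than silently undershooting.
* Connectivity is baseline 0.3 plus configured severity/covariate/SNP
  effects plus correlated Gaussian noise. Components are equicorrelated at
  0.35 by default (the published component-correlation matrix is in
  supplementary material we do not reproduce; 0.35 reflects components
  sharing one seed); a full matrix can be supplied. noise_sd = 0.12 was
  chosen so that the interaction SE at n = 134 lands on the published
  ~0.0005 scale, making injected β ≈ 0.002 effects land at the published
  t ≈ 4 scale.
* The generator emulates *tables*, not physiology: no raw BOLD series, no
  genotyping intensities, no population structure beyond block LD, no
  site/motion artefacts. Passing tests therefore validate the inferential
  machinery under the assumed model, not robustness to real-data
  violations of it.

Vertex maps are iid smooth Gaussian fields per subject (same graph
smoother as the cluster null) with an optional signal patch whose
amplitude scales with a per-subject weight (pass dosage × severity to
plant an interaction).

## Numerical and design choices

* OLS is QR-based with explicit rank checks; the permutation and
  vertex-wise paths reuse the same algebra in vectorised form and are
  tested against the scalar path and statsmodels.
* Fisher-z is the stored connectivity phenotype (variance-stabilising,
  standard for seed connectivity); raw r is available via the `cap`/config
  options. A perfect |r| = 1 raises by default — degenerate fixtures
  should fail loudly — with opt-in clipping.
* Runs are averaged in z-space with equal weights regardless of retained
  frame counts; frame-count weighting is a flag.
* All Monte-Carlo p-values use the add-one (b+1)/(B+1) convention.
* Every stochastic routine takes a seeded `numpy.random.Generator` or an
  integer seed; equal seeds give bit-identical output.

## Validation problem sizes

The shipped validation (test suite + `scripts/acceptance.py`) runs the
FWER calibration at 500 null cohorts × B = 2000 (the same 7-SNP × 8
component family as the defaults), parameter recovery over 500 replicate
cohorts, the sign-pattern check over 200 cohorts, the exhaustive-oracle
comparison at n = 7 (5040 permutations vs B = 5000), the Šidák comparison
at m = 6 independent SNPs (B = 4000, n = 400), and the cluster checks on
a 2500-vertex grid mesh (B = 199). These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances while keeping the whole
validation under a few minutes on one CPU.

## Known limitations

* The correction is single-step max-T; step-down refinement and FDR are
  out of scope.
* No mixed models, kinship adjustment, robust/sandwich errors, or
  genome-wide scanning; the engine is built for candidate-panel families.
* The cluster module's smoothness parameter is not calibrated to any
  cortical surface geometry; its p-values are internally consistent, not
  transferable across meshes.
* The simple-effect p-values use df = n − 2 − k with k the number of
  partialled covariates; published per-genotype correlations of the kind
  this reproduces are often ambiguous about k, so small p discrepancies
  against published values are expected.
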