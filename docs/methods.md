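# Methods

`pedbp` simulates longitudinal systolic and diastolic blood pressure
(SBP, DBP) on extended pedigrees, together with hypertension diagnosis,
antihypertensive treatment (including a pharmacogenetic nonresponse
interaction), smoking, and a heritable null trait Q1, and re-estimates
every generating parameter from the simulated output. This note records
the model, its assumptions, the calibration mathematics, and the design
choices that were genuinely open.

## Study design emulated

Twenty extended families of 21–76 members (three or more generations,
including two monozygotic twin pairs in distinct families) are generated
synthetically: each family grows from a founder couple by sampling
offspring counts (2–5 per couple) and marrying in founder spouses until a
target size drawn uniformly from the configured range is reached. Exam-1
ages are assigned by generation depth (≈74 yr at the founder generation,
−21 yr per generation, SD 5, floor 16), and exams 2 and 3 sit at the fixed
offsets of +3.9 and +6.9 years. A fixed subsample (default 849) of
individuals is marked phenotyped. Sex, ages, pedigree structure, the
phenotyped subsample, and genotypes at the functional and interaction
variants are constant across replicates; everything else is regenerated
per replicate from a counter-based seed, so replicates are independently
reproducible.

Real pedigrees of this design contain marriage loops and other structure
we do not attempt to match beyond size, depth, and twin counts.

## Genotypes

Variants are biallelic, on odd autosomes only, and treated as unlinked.
Gene dropping draws founder genotypes at Hardy–Weinberg equilibrium at
each variant's minor allele frequency (MAF) and transmits one uniformly
chosen allele per parent; MZ twins share a genome (copied, not redrawn;
the additive relationship matrix collapses each twin pair to one genome
before the recursive tabular method, so twins get off-diagonal entries
equal to their diagonal). Unlinked loci give the closed form
Var(dosage) = 2pq used throughout for validation. No linkage
disequilibrium, X chromosome, or genotyping error is simulated, so tests
passing here say nothing about LD-driven phenomena in real data.

## Genetic effects

Three variant classes carry effects:

| class | count | effect |
|---|---|---|
| functional (coding) | 55 packaged | signed per-allele betas, up to ±11.07 mmHg |
| polygenic background | 1000/replicate, MAF > 0.4 | ±0.11187 (SBP), ±0.08786 (DBP) mmHg, half each sign |
| CYP3A43 interaction | 3 | no direct effect; carriers are medication nonresponders |

The packaged functional catalog carries the published per-variant betas
and MAFs verbatim. For building new catalogs, the coding effect-size
generator is

    |beta| = percentile(PP2S) · PP2S² · |ρ_g| · k · l

with PP2S the PolyPhen-2 damage score, ρ_g the transcript–trait genetic
correlation, k a global and l a gene-specific constant (defaults 1; the
published catalog's constants are not recoverable from the betas). The
sign rule is separate: deleterious coding variants reduce gene function
and therefore push the trait *against* the transcript–trait correlation;
regulatory variants follow it. The percentile is taken within the set of
selected coding variants, in [0, 1]. ρ_g enters the magnitude as |ρ_g|,
with direction handled solely by the sign rule.

Per-person genetic values are dosage-weighted beta sums, with the
functional and background components each centered to sample mean zero
(the background centering is part of the model; centering the functional
component as well makes the configured trait means exact).

## Heritability fixing

Total narrow-sense heritability is fixed at h² = 0.279 (SBP) and 0.317
(DBP). Because the genetic values in a replicate are one realized
gene-drop vector g — not a fresh draw from N(0, Va·A) — the package
calibrates the environmental variance v against the estimator that will
be used on the output: v solves

    argmin_{h²} E_e[ −2·restricted loglik(h²; g + e) ] = h²_target,
    e ~ N(0, v·I),

where the expectation replaces the data quadratic form y'Py by
g'Pg + v·tr(P) and everything is evaluated in the eigenbasis of the
relationship matrix A (one eigendecomposition per study). Root-finding
over v is monotone and converges to machine precision. The naive
alternative, v = Var̂(g)·(1−h²)/h², is exposed as
`calibrate_environment` but is *not* used by the study pipeline: the
sample variance of g over correlated relatives is not the A-structured
variance REML measures, and using it left mean REML recoveries ≈0.03 too
high. With the REML-objective calibration, 40-replicate means sit within
one Monte-Carlo SE of both targets.

## Covariate model and environments

Mean trait values are

    E[DBP] = 71 − 3.715·female + (0.158·female)·(age − 37.74)
    E[SBP] = 122 − 5.565·female + (0.266·male + 0.708·female)·(age − 37.74)

(mmHg; DBP has no age slope in males). The six environmental components
(DBP and SBP at exams 1–3) are one joint zero-mean Gaussian per person,
independent between persons, with the fixed 6×6 correlation matrix of the
model (all pairwise values; the matrix is positive definite as given —
smallest eigenvalue 0.16 — but a nearest-correlation repair via
`statsmodels.corr_nearest` is applied automatically if a user-supplied
matrix is not, logging the largest entry perturbation). Per-trait
environmental variance is stationary across exams (the calibrated v at
every exam). Genetic values are identical across exams, so the
within-trait genetic correlation over time is exactly 1, and no bounds
are placed on simulated values (SBP < DBP can occur). The SBP–DBP genetic
correlation is implied by the shared functional betas, not configured.

## Treatment, diagnosis, smoking

Hypertension is SBP > 140 or DBP > 90 (strict) on *raw*, pre-medication
values, or current medication use. At each exam the fraction of current
hypertensives on medication targets (0.55, 0.67, 0.82): the incident
probability for untreated hypertensives is solved from the realized
carry-over counts so the marginal fraction matches (a plain per-exam
Bernoulli variant is available via
`TreatmentParams.marginal_treatment_matching=False`). Treatment and
(for those treated at exam 1) affection status persist regardless of
later values; untreated hypertensives may revert. Treated responders
have 6.2/7.9 mmHg subtracted from observed SBP/DBP; carriers of any of
the three deleterious CYP3A43 coding variants (dosage ≥ 0.5, i.e. one
minor allele for integer dosages) are nonresponders, unchanged by
treatment. Smoking: 22.9 % prevalence at exam 1, each smoker quitting
with probability 1.45 % per subsequent exam, never resuming; smoking
affects nothing.

## Null trait Q1

Q1 (exam 1 only) is Gaussian with additive covariance h²·σ²·A (h² = 0.68,
σ² = 1) plus independent residual, sampled through the PSD square root of
A (eigendecomposition; A is singular when MZ twins are present, so a
Cholesky factor is not available). Fixed effects default to +0.3 in
females and −0.01/yr of centered age — the magnitudes are free choices of
this package; only their signs are part of the model. No genotype enters
Q1, so every marker association is a false positive by construction; the
mixed-model score scan is exactly χ²₁-calibrated here because the trait
really is Gaussian and independent of genotype.

## Estimation suite

* REML: single random effect, eigendecomposition of A, restricted
  likelihood profiled over total variance and maximized over h² by
  bounded scalar minimization (xatol 1e-8, boundary candidates checked
  explicitly); SE from the numerical curvature; estimates clamped to
  [0, 1]. `estimate_heritability_many` shares one eigendecomposition
  across replicate traits.
* Covariate recovery: OLS on female indicator and sex-stratified centered
  age. When pooling replicates (which share one fixed genotype draw) or
  relatives, family-cluster-robust SEs are used; naive SEs are
  anticonservative there.
* Null scan: score test (g'Py)²/(g'Pg) with P from the fitted null
  mixed model, vectorized over variants in the rotated basis;
  monomorphic variants are skipped and counted.
* Rates and environmental correlations: empirical fractions with
  binomial SEs, empirical Pearson correlations with Fisher-type SEs.

## Problem sizes and reproducibility

The validation and acceptance computations use the full-scale study
design (20 families, ~849 phenotyped) with 20 replicates for the
blood-pressure heritabilities and 50 for Q1, rates and covariate
recovery; environmental correlations use 100,000 component draws; the
null scan uses one replicate's ~1058 variants. All randomness flows from
one base seed through tagged `numpy` SeedSequence hierarchies; a study
run is fully reproducible (byte-identical files) from its configuration
alone, and any replicate can be regenerated without the others.

## Known limitations

* One realized study per seed: with genotypes fixed across replicates,
  pooled estimates (notably the sex offsets) retain a study-level random
  deviation of order 0.3 mmHg that more replicates cannot shrink — real
  studies have exactly this property.
* The packaged functional catalog holds the 55 largest published coding
  variants, not the full >1400-variant architecture, so this package's
  genetic architecture is lumpier than the original; the polygenic
  background supplies the remaining heritability.
* Published per-variant variance-explained percentages were computed
  against unprinted real-dosage denominators; with the package's
  Hardy–Weinberg denominators (σ²_SBP = 217.5, σ²_DBP = 104.0, calibrated
  once from the top catalog row) they are reproduced only approximately
  and are reported, not asserted.
* No LD, no imputation uncertainty, no missing data, no real-pedigree
  loop structure.
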