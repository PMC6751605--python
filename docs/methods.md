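# Methods

## The problem

Broiler breeding programs keep their purebred selection candidates in a
bio-secure (B) environment while commercial production happens under less
protected conditions (C).  Body weight expressed in B and in C behaves as
two correlated traits (genotype-by-environment interaction): variances are
heterogeneous, heritabilities differ, and the genetic correlation between
the two expressions is far below 1 (around 0.5 in the data this package
emulates).  Because candidates never have records in C, their merit for
commercial performance must be inferred from sibs tested in C — a
sib-testing design in which genomic information is particularly valuable,
since pedigree prediction can exploit at most the family-average half of
the genetic variance while marker-based relationships also capture
Mendelian sampling.

The package implements the complete evaluation chain for this setting:
simulation of the breeding program, sex-wise standardization, multi-trait
REML, pedigree BLUP (PBLUP) and single-step genomic BLUP (ssGBLUP), and
full/reduced cross-validation with the Legarra–Reverter (LR) statistics.

## Statistical models

**Univariate scaling model.** For each (sex, week, environment) cell,
body weight in grams follows

    y = Xb + Za + Wc + e,

with fixed factors hatch time-step, sire time-step, dam time-step and dam
age in 1-week classes; `a ~ N(0, A sigma_a^2)` with A the numerator
relationship matrix; `c ~ N(0, I sigma_c^2)` a dam permanent-environment
effect; `e ~ N(0, I sigma_e^2)`.  The cell's phenotypic SD is
`sqrt(sigma_a^2 + sigma_c^2 + sigma_e^2)` — the total variance is the only
SD this model defines — and every record is divided by its cell SD.

**Multi-trait model.** On the standardized scale, the four genetic traits
(BW5.B, BW6.B, BW5.C, BW6.C) are modelled jointly over eight record types
(4 traits x 2 sexes).  Standardization equalizes male and female genetic
variances and the between-sex genetic correlation is fixed at 1, so male
and female records of the same trait load on a *single* genetic effect per
animal (a reduced-rank parameterization): `a ~ MVN(0, A (x) Va0)` with Va0
4x4.  The maternal permanent-environment effect is likewise 4-variate per
dam, `c ~ MVN(0, I (x) Vc0)`.  Residuals are 8x8 structured: covariances
between sexes and between B and C are structural zeros; within a (sex,
environment) cell the week-5/6 pair shares a free 2x2 block.  ssGBLUP
replaces A by the combined matrix H whose inverse is A^-1 plus
(G_w^-1 - A22^-1) on the genotyped block, with G from VanRaden's method 1
(observed allele frequencies) and G_w = (1-omega) G + omega A22,
omega = 0.01.

**Variance components** are always estimated under the pedigree kernel:
with selective genotyping, REML under the genomic kernel is biased, and
the pedigree-based estimates are reused for all four EBV runs (PBLUP and
ssGBLUP, full and reduced data).

## REML implementation

The estimator is an EM-REML backbone with average-information (AI)
acceleration:

- Every iteration computes the exact EM update.  Its trace terms require
  selected entries of the inverse of the mixed-model coefficient matrix;
  these are obtained exactly from a simplicial sparse LDL' factorization
  (up-looking, elimination-tree based) followed by the Takahashi
  recurrences, both numba-compiled.  The elimination order is a minimum-
  degree ordering; the entry indices visited by the recurrences are
  resolved once per sparsity pattern and replayed on refactorizations.
- The AI (average-information) update is computed from matrix-free
  products — each AI column costs one triangular solve — and the Newton
  step is taken on the Cholesky-factor scale of each covariance block, so
  every step maps back into the positive-definite cone.  Levenberg
  damping handles directions with no information (for example a maternal
  covariance between recording windows that share no dams, which the
  study's recording plan genuinely produces).  If no damped AI step
  raises the restricted likelihood, the EM update (guaranteed uphill) is
  taken.
- EM updates are eigenvalue-floored at 1e-5 (relative to the block trace)
  so iterates stay strictly inside the SPD cone; estimated correlations
  may approach but not reach 1.  This matters because the week-5/week-6
  genetic correlation within an environment is ~0.96-0.99 and the MLE
  often sits essentially on the boundary.
- Convergence is declared when the Frobenius norm of the parameter update
  falls below `tol` (default 1e-5), or when the restricted log-likelihood
  has not improved by more than 1e-6 (1+|ll|) for 15 consecutive
  iterations, in which case the best-likelihood iterate is returned.  The
  plateau rule exists because boundary-adjacent covariances make the last
  digits of the update numerically noisy; it is the same pragmatic
  relaxation that production REML software applies.
- Several starting values (default 3, truth-agnostic variance splits) are
  run to guard against local maxima; disagreement between converged
  starts beyond 1e-3 relative is flagged.

The residual E-step handles animals with only one of the two weekly
records by exact conditional-expectation completion of the missing
residual, which keeps the update inside the SPD cone.  Identifiability of
the fixed effects is obtained by keeping all levels of the first factor
(hatch time-step, which absorbs the cell mean) and reference-coding the
remaining factors; columns that are still linearly dependent within a
record type (e.g. a dam-age class observed in a single hatch group) are
detected by pivoted QR and dropped.  EBV are invariant to these
estimable-function choices (tested).

## Mixed-model solvers

Small systems are solved densely (test oracle).  Production solves use
preconditioned conjugate gradients with a block-Jacobi preconditioner
(4x4 blocks per animal and dam, scalar for fixed equations), tolerance
1e-8 on the relative residual.  The single-step kernel is applied
matrix-free: the sparse A^-1 part explicitly, the dense genotyped-block
adjustment through the Kronecker identity
`(H^-1 (x) V^-1) v = (H^-1 V_mat) V^-1` on the (animal x trait) reshape,
so the H^-1 (x) Va0^-1 product is never materialized.

## The synthetic breeding program

The generator emulates the study design the analysis assumes: 16
time-steps (~2.5 generations) of overlapping-generation selection;
founders in time-step 0; parents selected from B-tested birds of the
previous 3 time-steps (truncation on the recorded B weight by default,
random mating optionally); each full-sib family split between B and C
(floor(prop_to_C x family size) members to C); sexes balanced 1:1 within
family.  Default scale: 8 sires and 16 dams per time-step, 12 offspring
per dam (~3,100 birds), 1,000 SNPs with founder MAF uniform on
(0.05, 0.5).

True breeding values are carried by additive SNP effects and gene
dropping, so genomic relationships carry real Mendelian-sampling signal
beyond the pedigree.  The 4-trait effect vectors are drawn MVN and then
rescaled so that the locus-weighted effect covariance
`sum_j 2 p_j q_j beta_j beta_j'` equals Va0 exactly.  The alternative —
forcing the founder *sample* covariance to Va0 — would push the effect
covariance away from Va0 by the inverse of the founder sampling noise
(~50 founders), making the Mendelian-sampling covariance inconsistent
with the founder covariance; no single Va0 would then describe the data.
With the effect-covariance scaling, founders deviate from Va0 only by the
sampling noise the animal model itself expects.

Phenotypes follow the model exactly on the standardized scale (baseline +
fixed effects + breeding value + dam effect + structured residual) and
are stored in grams after multiplication by the cell SD.  Defaults:
heritabilities 0.30 (B) and 0.35 (C), maternal ratio c2 = 0.035, genetic
correlation ~0.5 between environments and 0.96-0.98 between weeks within
an environment, residual week-to-week correlation 0.55, cell SDs and
means at realistic gram magnitudes (e.g. male BW5.B 2183 +- 213 g).
Fixed-effect level effects are drawn with SDs 0.25 (hatch time-step),
0.10 (parental time-steps) and 0.05 (dam age) on the standardized scale.
Dam age is uniform on 30-60 weeks (the analysis uses 1-week classes).

The default recording plan mirrors the study: B birds have only the
week-6 weight early (time-steps 1-10 of 16), week-5 on everyone plus
week-6 on a 33% random subset late; C testing starts at time-step 5 with
both weights, week-5 only late.  Selective genotyping flags all C birds,
all parents, and the top `prop_genotyped_B` fraction of B birds per (sex,
time-step) ranked on the fully recorded B weight (ties broken by
identifier).

What the generator does *not* emulate: linkage and LD structure (loci are
unlinked, so marker-trait associations come from relatedness only),
mutation, non-additive gene action, hatch-within-time-step structure, and
the scale of the real data (~70,000 birds, ~50,000 SNPs).  Passing tests
therefore demonstrate the correctness and the qualitative behaviour of
the method chain, not the numerical values attainable on a commercial
dataset.

## Cross-validation

The reduced dataset keeps records with hatch time-step <= cutoff (default
12/16 of the program); validation birds are B-environment birds hatched
after the cutoff, split into genotyped and non-genotyped groups.  For
each trait and group the package reports rho_f,r (correlation of EBV from
full and reduced data; indicator of population accuracy), b_f,r (slope of
EBV_f on EBV_r; dispersion, expectation 1) and d_f,r (mean difference;
bias, expectation 0), all on the standardized scale.  Standard errors are
nonparametric bootstrap over validation animals (default 1,000 resamples,
seeded); the d_f,r statistic is only reported on the standardized scale
because sex-wise scaling would split it into two gram-scale values.

In simulation, `expectation_check` compares rho_f,r with acc_r/acc_f
computed from true breeding values.  These expectations hold under the
model's own assumptions (random mating, correct components); with
selection or misspecification the deviations are themselves the quantity
of interest.

## Validation-scenario sizes

The acceptance suite runs scaled-down Monte-Carlo scenarios chosen as the
package's own study conditions:

- *Parameter recovery*: 8 replicates of a 10-time-step random-mating
  program with 12 sires / 48 dams per time-step (four dams per sire), 5
  offspring per dam (~2,500 animals, ~4,900 records), both weights
  recorded in both environments and half of each family tested in C.
  The mating ratio matters: with parents never recorded in C, the sire
  half-sib covariance is the only contrast isolating additive variance
  for the C traits from the dam effect, and the between-dam-within-sire
  contrast isolates the maternal component; the study-style sparse
  recording plan at desk scale leaves h2(C) nearly unidentified and the
  per-replicate estimates collapse into a maternal/genetic confounding
  mode.
- *LR expectations*: 10 replicates, 12 time-steps, 18 sires / 72 dams per
  time-step (~10,500 animals), cutoff 8, giving ~290 validation families;
  the rho_f,r vs acc_r/acc_f comparison needs hundreds of validation
  families before its Monte-Carlo noise drops below the 0.05 band.
- *Directional genomic benefit*: 10 replicates of the default
  selective-genotyping program (~3,100 animals, genotyping fraction 0.25
  in B), EBV from true components.

## Known limitations

- The asymptotic standard errors of the covariance estimates are not
  computed (the AI matrix at convergence would provide them); LR
  statistics carry bootstrap SEs instead.
- Model-based (individual) accuracies are only available through the
  dense solver on toy systems, matching the practical situation in which
  the inverse of the single-step coefficient matrix is out of reach.
- REML under the genomic kernel is deliberately not offered.
- The simplicial factorization targets desk-scale problems (up to a few
  tens of thousands of equations); national-evaluation scale would need
  supernodal methods or trace approximations.
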