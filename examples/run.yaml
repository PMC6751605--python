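# Complete annotated pipeline configuration.
#
# Every field is optional; the values shown are the defaults used by
# `gxe run` when no config is given (except where noted).

sim:
  n_time_steps: 16        # selection/testing periods (~2.5 generations)
  n_sires_per_ts: 8       # sires selected per time-step
  n_dams_per_ts: 16       # dams selected per time-step
  offspring_per_dam: 12   # full-sib family size
  prop_to_C: 0.3          # fraction of each family tested in C (floor rule)
  prop_genotyped_B: 0.3   # top fraction of B birds genotyped per sex/time-step
  n_snps: 1000            # unlinked SNPs carrying the true breeding values
  maf_range: [0.05, 0.5]  # founder minor-allele frequencies (uniform)
  selection_trait: auto   # rank on the fully recorded B weight of each TS
  dam_age_range: [30, 60] # dam age in weeks, uniform; 1-week model classes
  parent_ts_window: 3     # parents drawn from this many preceding TS
  random_mating: false    # true = random parent draws (no truncation)

# Ground-truth covariance scale; omit the section for the defaults
# (h2 0.30 in B / 0.35 in C, maternal ratio 0.035, rg(B,C) ~ 0.5).
truth:
  h2_b: 0.30
  h2_c: 0.35
  c2: 0.035

omega: 0.01               # weight on pedigree relationships in G_w
snp_missing_max: 0.05     # QC: drop SNPs with missing rate >= this
animal_callrate_min: 0.95 # QC: drop animals with call rate <= this
maf_min: 0.01             # QC: drop SNPs with MAF < this
pcg_tol: 1.0e-8           # PCG relative-residual tolerance
reml_tol: 1.0e-5          # Frobenius norm of the REML update
reml_max_iter: 200
n_reml_starts: 3          # REML restarts (different starting values)
cutoff_ts: 12             # reduced data keep hatch TS <= cutoff
n_boot: 1000              # bootstrap resamples for LR standard errors
seed: 0
variance_components: reml # or "true" to reuse the simulation truth
scaling: model            # univariate REML per cell; or "sample" (raw SD)
outlier_sd: 4.0           # records beyond this many SD are dropped
use_genomics: true        # false = pedigree-only evaluation
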