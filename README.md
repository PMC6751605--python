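# gxeblup

Genomic evaluation of broiler body weight under genotype-by-environment
interaction (G×E), for quantitative geneticists and breeding-program
analysts working with sib-testing designs.

## The problem

Purebred broiler selection candidates are raised in a bio-secure breeding
environment (B); commercial production happens under harsher conditions
(C).  Body weight at 5 and 6 weeks expressed in B and in C behaves as
correlated traits with a genetic correlation of only ~0.5, heterogeneous
variances and different heritabilities — a strong G×E interaction.  The
candidates themselves never have C records; their commercial merit must
be inferred from sibs tested in C.  This package implements the complete
evaluation chain for that design:

- **Multi-trait model.**  Records are standardized by sex-wise phenotypic
  standard deviations estimated from a univariate animal model
  `y = Xb + Za + Wc + e` per (sex, week, environment) cell.  The joint
  model then treats BW5.B, BW6.B, BW5.C, BW6.C as four genetic traits
  over eight record types, with sex-shared genetic effects
  `a ~ MVN(0, A ⊗ Va0)` (reduced rank: the between-sex genetic
  correlation is 1), a 4-variate maternal permanent-environment effect
  `c ~ MVN(0, I ⊗ Vc0)`, and an 8×8 structured residual whose
  between-sex and between-environment covariances are structural zeros.
- **Variance components** by EM/AI-REML with exact trace terms from a
  sparse LDL' factorization with Takahashi selected inversion, always
  under the pedigree kernel (selective genotyping biases genomic-kernel
  REML).
- **EBV** by PBLUP (pedigree relationship matrix A) or single-step GBLUP,
  where A is replaced by the combined matrix H:
  `H⁻¹ = A⁻¹ + [0 0; 0 Gw⁻¹ − A22⁻¹]`, `Gw = 0.99 G + 0.01 A22`, and G
  is VanRaden's method-1 genomic relationship matrix.  Systems are solved
  by preconditioned conjugate gradients.
- **Validation** by the Legarra–Reverter full/reduced comparison: EBV are
  predicted from all records and from records truncated at a cutoff
  time-step; for the validation birds, ρ_f,r (correlation; population
  accuracy indicator, expectation acc_r/acc_f), b_f,r (slope; dispersion,
  expectation 1) and d_f,r (mean difference; bias, expectation 0) are
  reported with bootstrap standard errors.
- **Simulation.**  Because the motivating data are proprietary, a
  first-class generator reproduces the program structure: overlapping
  generations over 16 time-steps, full-sib families split between B and
  C, parents selected from B only, true breeding values carried by SNP
  effects with gene dropping, and top-phenotype selective genotyping in
  B.  See `docs/methods.md` for every modelling and numerical choice.

## Worked example

```python
from gxeblup import RunConfig, SimConfig, run_pipeline

config = RunConfig(
    sim=SimConfig(seed=5, n_time_steps=6, n_sires_per_ts=4,
                  n_dams_per_ts=8, offspring_per_dam=8, n_snps=300),
    seed=5, variance_components="true", scaling="sample", n_boot=150,
)
report = run_pipeline(config)
print(report.descriptive.head(4).to_string(index=False))
print(report.lr.query("group == 'genotyped'")[
    ["model", "trait", "rho", "b", "d"]].round(3).to_string(index=False))
```

prints

```
 week sex env  n  mean_g  sd_g    cv
    5   F   B 74    1962   196 0.100
    5   F   C 35    1474   263 0.178
    5   M   B 70    2275   214 0.094
    5   M   C 45    1679   294 0.175
  model trait   rho     b     d
  PBLUP BW5.B 0.841 1.372 0.210
  PBLUP BW6.B 0.855 1.370 0.209
  PBLUP BW5.C 0.853 1.368 0.115
  PBLUP BW6.C 0.850 1.368 0.112
ssGBLUP BW5.B 0.793 1.030 0.176
ssGBLUP BW6.B 0.811 1.043 0.171
ssGBLUP BW5.C 0.800 0.992 0.090
ssGBLUP BW6.C 0.796 0.991 0.088
```

The descriptive block is the report-style summary (record counts, means
and SDs in grams, coefficient of variation): B birds are heavier but less
variable than their C sibs, so their CV is lower.  The validation block
shows the LR statistics for the genotyped validation birds of this small
demo.  A slope b_f,r far above 1 means the full-data EBV spread out much
more than the reduced-data EBV predicted (over-dispersion of the pedigree
prediction under selective genotyping); the single-step model brings the
slope back to ~1 and reduces the bias d_f,r for the genotyped birds.

The same analysis is scriptable from the shell:

```bash
gxe simulate --seed 1 --out data/          # write pedigree/phenotypes/genotypes
gxe run --config examples/run.yaml --seed 1 --out results/
```

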