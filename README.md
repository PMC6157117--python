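# famblup

G-BLUP genomic prediction, PEV-based reliability and variance-component
linkage mapping for family studies — with a gene-dropping simulator that
makes the whole pipeline testable without access-restricted human data.

## The problem

For complex traits, single associated markers predict very little.  Genomic
best linear unbiased prediction (G-BLUP) instead uses *all* markers at once,
through a relationship matrix, to predict each individual's total additive
genetic value — the **empirical genetic value (EGV)**.  Two practical
questions decide whether EGVs are usable in human family studies:

1. **How reliable is each individual's EGV, and what drives that
   reliability?**  The choice of relationship matrix (pedigree expectations
   vs. marker-based estimates) and the number of close relatives an
   individual has in the data set both matter.
2. **Can EGVs increase the power of linkage mapping?**  An EGV is a
   phenotype with the (structured) environmental variance stripped away, so
   linkage scans on EGVs should show stronger signal at true loci.

`famblup` implements the full analysis for both questions: simulation of
multigenerational family data with recorded identity-by-descent, three
relationship-matrix constructions, REML + Henderson mixed-model fitting with
per-individual prediction error variance, relatedness summaries, and
variance-component LOD scans with an EGV-vs-raw-trait comparison.

## The model

    y = Xb + Zu + e,   u ~ N(0, σ²g K),   e ~ N(0, σ²e I)

* `K`: additive relationship matrix, unit diagonal — from the pedigree
  (tabular method), from SNPs (VanRaden GRM, optionally with inverse local-r²
  LD weights), or from moment-based IBD-sharing estimates.
* REML variance components via eigendecomposition + profiled likelihood.
* EGVs `û` and their prediction error variances `PEV_i = σ²e·C^{uu}_ii` from
  Henderson's mixed-model equations; per-individual accuracy
  `EA_i = sqrt(1 − PEV_i/σ²g)`.
* SDR (second-degree-relative count): number of relationship coefficients
  above 0.25; accuracy is regressed on SDR.
* Linkage: at each position, `V = σ²q·K_locus + σ²g·K_poly + σ²e·I` vs. the
  `σ²q = 0` null; LOD-on-LOD regression of the EGV scan on the raw-trait
  scan, with a one-sided test of slope > 1.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import famblup as fb

cfg = fb.SimulationConfig(n_families=12, generations=2, mean_sibship=3,
                          n_snps=800, n_chromosomes=4, h2=0.4,
                          household_variance_fraction=0.2, seed=5)
ped = fb.simulate_pedigree(cfg)
panel, ibd = fb.simulate_genotypes(ped, cfg)
pheno = fb.prepare_traits(fb.simulate_phenotypes(ped, panel, ibd, cfg))

kin = fb.build_kinships(ped, panel)          # pedigree / GRM / LD-GRM / IBD
fit = fb.fit_gblup(pheno, fb.ModelSpec("trait_pre"), kin["grm_ld_weighted"])
print(f"h2_hat = {fit.components.h2:.3f}")
print(f"mean accuracy = {fit.accuracy.mean():.3f}")

sdr = fb.count_sdr(kin["grm_ld_weighted"])
reg = fb.regress_accuracy_on_sdr(fit.accuracy, sdr)
print(f"EA-on-SDR slope = {reg.slope:+.4f}  R2 = {reg.r_squared:.3f}")
```

prints (seed 5):

```
h2_hat = 0.332
mean accuracy = 0.686
EA-on-SDR slope = +0.0080  R2 = 0.208
```

— the REML heritability estimate is 0.33 against a simulated 0.4 (a small
235-person pedigree leaves REML noisy), the average EGV accuracy is ≈ 0.69,
and accuracy rises by ≈ 0.008 per additional close relative, explaining
≈ 21% of its variation across individuals.

The same experiment, end to end with reports on disk:

```
famblup run-all --seed 5 --out runs/demo
```

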