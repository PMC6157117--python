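# Methods

`famblup` studies the reliability of genomic prediction in family data: how
well G-BLUP recovers each individual's total additive genetic value (the
*empirical genetic value*, EGV), how that reliability depends on the choice
of relationship matrix and on how many close relatives an individual has, and
how much statistical power genetic linkage mapping gains when EGVs replace
raw phenotypes.  Because suitable human family data (large multigenerational
cohorts with dense genotypes and repeated pre/post-intervention phenotypes)
are access-restricted, the package ships a gene-dropping simulator whose
output has the same statistical structure, with the advantage that the true
identity-by-descent (IBD) state of every allele is recorded.

## The mixed model

For a trait vector **y** on the phenotyped subset of individuals,

    y = X b + Z u + e,    u ~ N(0, σ²g K),    e ~ N(0, σ²e I),

where **X** holds the intercept and covariates (age, sex, study center,
smoking by default), **K** is an additive relationship matrix over *all*
individuals (including genotyped-but-unphenotyped ones, who receive
predictions through their relatives), and **Z** is the 0/1 incidence of
records onto individuals.

*Variance components* are estimated by REML.  After one eigendecomposition
of ZKZᵀ the restricted likelihood is profiled over the heritability ratio
h² = σ²g/(σ²g+σ²e), so each candidate h² costs a weighted least-squares
solve.  A 51-point grid locates the basin, a bounded scalar optimizer
refines the optimum to 1e-8, and a guard ensures the returned optimum never
falls below any grid point.  Boundary estimates (ĥ² = 0 or → 1) are reported,
not raised; the pipeline flags σ²g at the zero boundary.

*EGVs* come from Henderson's mixed-model equations with λ = σ²e/σ²g; K is
inverted through its eigendecomposition with eigenvalues floored at 1e-8
(genomic matrices are near-singular).  The prediction error variance of
individual *i* is PEV_i = σ²e·C^{uu}_ii from the u-block of the inverse
coefficient matrix — it includes fixed-effect uncertainty, the standard
interpretation.  The per-individual accuracy is

    EA_i = sqrt(1 − PEV_i / σ²g),

clipped into [0, 1] (clipping can occur for unphenotyped individuals with no
phenotyped relatives).  σ²g here is the REML estimate from the same fit,
mirroring standard reliability reporting in which the base-population
variance is unobservable.  PEV equals the mean squared error of the EGV in
the absence of bias; `pev_calibration` verifies this identity by Monte
Carlo.

## Relationship matrices

All matrices are on the additive-relationship scale (twice the kinship
coefficient) and are scaled to an exact unit diagonal before use, so the
three constructions are directly comparable and the second-degree-relative
threshold of 0.25 has a single meaning.  The 0.25 threshold is applied on
this unit-diagonal scale (it is the expected value for exact second-degree
pairs, so empirical estimates scatter both sides of it); the threshold is
configurable.

* **pedigree** — the numerator relationship matrix A by the recursive
  tabular method; handles inbreeding (A_jj = 1 + A_{fm}/2).
* **grm_unweighted** — VanRaden GRM, G = MMᵀ/Σ2p(1−p), dosages centered at
  2p̂ with allele frequencies estimated from the full sample (founder-only
  estimation would be marginally less biased but the full-sample default is
  the common practice); monomorphic SNPs dropped.
* **grm_ld_weighted** — the same with per-SNP weights w_j = 1/Σ_k r²_jk over
  a cM window (including k = j).  A SNP whose signal is replicated by
  neighbours in LD contributes proportionally less, which removes the
  over-counting of dense regions.  This is a deliberately simple,
  transparent LD adjustment — the weighting *principle*, not a
  reimplementation of any specific package's solver.
* **ibd_moment** — method-of-moments IBD probabilities P(IBD=0,1,2) per pair
  from identity-by-state counts and allele-frequency expectations, clipped
  to [0,1] and renormalized; relationship = P1/2 + P2 (pi-hat).  Diagonal
  set to 1 (no inbreeding estimation).  This is the classical
  moment construction, a transparent stand-in for model-based
  (hidden-Markov) IBD inference, capturing the property under study —
  relatedness estimated through realized sharing rather than LD-corrected
  allele counts.

Genomic matrices are PSD-repaired (eigenvalues clipped at 1e-8 — the
Frobenius-nearest clipped reconstruction) *before* unit-diagonal
normalization, so downstream REML solves are well posed.

## Linkage scans

At each map position the variance is partitioned as

    V = σ²q K_locus + σ²g K_poly + σ²e I,

with K_locus the realized IBD-sharing matrix at the position (taken from
gene-dropping truth: multipoint IBD estimation is a separate problem and
using the truth isolates the question of interest — whether EGV traits carry
more mappable signal).  LOD = log10 of the restricted-likelihood ratio
against σ²q = 0, floored at 0.  The total variance is profiled out and the
two free variance proportions are maximized over the simplex by a coarse
grid plus Nelder-Mead in softmax coordinates (tolerance 1e-6); softmax
coordinates let the optimizer approach boundaries without stalling, which
matters because an EGV trait — itself a smooth genetic prediction — drives
the residual proportion near zero.  Both hypotheses share a residual floor
of 1e-6 of the total variance so that LOD cannot arise from one model
reaching closer to the degenerate zero-residual boundary than the other.

Two design choices deserve emphasis:

* **The scan's polygenic kernel is the pedigree matrix by default**, while
  the EGVs come from the genomic-matrix fit.  Scanning an EGV with the same
  matrix that produced it is degenerate: the polygenic null then absorbs the
  EGV's entire covariance and every LOD collapses to zero (verified
  empirically).  Separating the two — genomic prediction upstream,
  pedigree-based mapping machinery downstream — matches how such analyses
  are actually chained and keeps the comparison meaningful.
* **Covariates are not refitted in the EGV scan** (intercept only): the
  G-BLUP fit already absorbed them.  The EGV scan uses the same individuals
  as the raw-trait scan (phenotyped ones), isolating the effect of the trait
  definition from sample-size effects.

For the LOD-on-LOD comparison the scans are thinned to ≥ 5 cM spacing
(configurable) to mitigate the autocorrelation of LOD along the genome, then
EGV-scan LOD is regressed on trait-scan LOD over all thinned positions
(peak-only regressions discard most of the information).  The one-sided test
of slope > 1 uses t = (slope−1)/se with n−2 degrees of freedom; the Spearman
rank correlation of the two scans measures locus-rank preservation.

## The synthetic-data generator

The generator emulates a two-center family study of a log-scale metabolic
trait measured twice before and twice after an intervention:

* **Pedigree**: `n_families` independent families; a founder couple begets
  `1 + Poisson(mean_sibship − 1)` children per couple; offspring of
  non-terminal generations marry unrelated immigrant founders.  Defaults
  (60 families, 2 descendant generations, mean sibship 3) give ≈ 1000
  individuals in three-generation families.
* **Genotypes**: founder haplotypes are drawn per SNP with a latent-uniform
  copying scheme — the latent uniform is kept from the previous SNP with
  probability exp(−d/ld_block_length_cM) and redrawn otherwise — which
  yields local r² decaying with map distance while preserving each SNP's
  allele frequency exactly.  Non-founders are gene-dropped with Haldane
  (Poisson, no interference) recombination on evenly spaced maps
  (default 10 chromosomes × 100 cM, 5000 SNPs, MAF ~ U(0.05, 0.5)).  The
  founder origin of every transmitted allele is recorded, giving exact
  realized IBD at every SNP.
* **Phenotypes**: trait = fixed covariate effects (age 0.008/yr, male +0.15,
  center +0.10, smoking +0.20 on the log scale, around an intercept of 3.0)
  + polygenic value + optional QTLs + household effect + residual.  The
  polygenic value is infinitesimal by default (founders N(0, h²); offspring
  midparent + N(0, h²/2) Mendelian sampling, the non-inbred approximation)
  or, alternatively, the standardized sum of `n_causal` SNP effects.  QTLs
  are standardized single-SNP effects placed mid-chromosome (configurable),
  each contributing its `qtl_fraction` of variance; they exist so linkage
  experiments can combine a mappable locus with a polygenic background.
  Households are nuclear families (a couple plus its unmated offspring);
  household effects are shared within household.  Variance fractions are
  relative to the non-covariate variance: h² + Σqtl + household + residual
  = 1.  Each time point receives an independent residual; the post
  measurement adds `treatment_mean_shift` (−0.3 default, an
  intervention that lowers the trait); each time point is observed as
  `replicate_measurements` copies with N(0, measurement_error_sd²) error,
  averaged at ingestion (`prepare_traits`), mirroring the usual averaging of
  replicate assays.  `round(missing_phenotype_rate·n)` individuals keep
  genotypes but lose all trait values.
* **Seeds**: one master seed; each stage (pedigree, genotypes, phenotypes)
  derives an independent substream from a fixed labelled offset, so outputs
  are bytewise reproducible and stages can be re-run independently.  The
  random draws of each stage are consumed in a documented order that tests
  replay independently.

What the generator does *not* model: realistic human LD maps and
recombination hot spots, genotyping error or missing genotypes, X
chromosome, non-additive genetic effects, ascertainment.  Consequently,
passing tests show that the *methods* behave as claimed under their own
assumptions (additive polygenic trait, known pedigree, clean genotypes) —
not that the numerical results would transfer to any particular real cohort.

## Problem sizes and numerical choices

Test and acceptance workloads are scaled for a single CPU: the prediction
experiment uses ≈ 1000 individuals × 2000 SNPs (kinship estimation error
~0.02 for unrelated pairs, ample for thresholding at 0.25); the genomic-vs-
pedigree concordance check uses 20 000 weakly linked SNPs on ≈ 260
individuals; linkage experiments use ≈ 500 individuals, 3 chromosomes, scan
points every 25 cM with three QTLs (30/20/10% of variance) over a 20%
polygenic background and 20% household variance — an architecture with
enough distinct, graded real signal that locus ordering between two scans is
informative.  The REML grid/refinement tolerances (1e-8), the PSD floor
(1e-8), the scan optimizer tolerance (1e-6) and the shared residual floor
(1e-6) are stated above; degenerate regressions (zero-variance accuracy) and
failed scan positions return flagged values rather than aborting the
pipeline, and any failed stage is recorded in the run report and signalled
with a nonzero exit from the CLI.

## Known limitations

* The LD weighting and moment-IBD constructions are intentionally simple
  analogs of production LD-aware kinship estimators; they reproduce the
  qualitative behaviour (LD correction; sharing-based relatedness), not any
  specific software's output.
* Locus IBD matrices come from simulation truth; with estimated multipoint
  IBD the linkage contrasts would be attenuated by IBD-estimation noise.
* EGV-based scan LODs are not calibrated null statistics: the EGV's
  covariance is not exactly representable by the scan's variance model, so
  EGV LODs are interpreted comparatively (against the raw-trait scan), as in
  the source analysis, not against nominal significance thresholds.
* Accuracy is PEV-based, not hold-out-based; the two agree only under the
  model's own assumptions.
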