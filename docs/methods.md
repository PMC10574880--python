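# Methods

This note documents the models, conventions and deliberate design
choices behind `germcore`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Mixed model and BLUP

Per quantitative trait the observation model is

    y = μ1 + Z g + W b + T i + e

* `g` — genotype (accession) effects, `N(0, σ²_g I)`;
* `b` — block-within-environment effects, `N(0, σ²_b I)`; a location ×
  year combination is one "environment", and trial and environment are
  treated as the same stratum;
* `i` — genotype × environment interaction, `N(0, σ²_ge I)`;
* `e` — residual, `N(0, σ²_e I)`.

Only the grand mean is fixed. Variance components are estimated by
EM-REML on Henderson's mixed-model equations. EM was chosen over
average-information updates because germplasm evaluation data are
sparse and severely unbalanced (each accession visits a random subset of
environments, records missing at random), and EM is monotone in the
restricted likelihood and cannot step outside the parameter space; the
cost is slow convergence when a component approaches zero. Numerical
conventions:

* convergence when the restricted log-likelihood changes by < 1e-6,
  cap of 200 iterations (non-convergence is a warning, not an error —
  the cap typically only binds when a component is collapsing and the
  remaining estimates are already stable);
* variance floor 1e-8: components are clamped there rather than at 0 so
  the equations stay solvable;
* degenerate strata are dropped with a logged warning instead of
  failing: the interaction term when only one environment is present,
  the block term when there is a single block level;
* zero-variance data (all `y` equal) short-circuits to every component
  at the floor;
* BLUPs are obtained by solving the same equations at the REML
  estimates via Cholesky; an exactly singular system falls back to a
  pseudo-inverse with the condition number logged. Accessions with no
  records for a trait are absent from its BLUP table, not zero-filled.

Broad-sense heritability is reported on an entry-mean basis,
`h² = σ²_g / (σ²_g + σ²_ge/n_env + σ²_e/(n_env n_rep))`, with `n_rep`
the mean number of blocks per environment rounded to an integer. The
formula is a documented convention of this package — several entry-mean
variants exist and data sources rarely state which was used; the choice
only affects reporting, not ranking.

## Thematic selection

Themes are configuration: a trait list with a direction each, optional
hard filters, and a target size. Because no canonical rule exists for
combining several traits' BLUPs into one ordering, the composite score
is the equal-weight mean of per-trait ranks. Rank means are scale-free
(invariant under any monotone transform of a single trait's BLUPs,
which the suite checks) and insensitive to traits with very different
genetic variances. Accessions carrying BLUPs for fewer than half of a
theme's traits are excluded rather than imputed. All ties break on
accession id so identical inputs give identical collections.

Hard eligibility filters come in two kinds: comparators on numeric
values (tested on the BLUP-predicted value `μ + ĝ` when the trait was
modelled, else on the modal qualitative score) and allowed-class sets
(tested on modal qualitative scores). An accession with no value for a
filtered trait is ineligible: hard filters require evidence.

Truncation keeps the top `n_target`; if fewer survive the filters, all
survivors are kept with a warning.

## Duplicate pruning

IBS is the average proportion of shared alleles under the dosage
metric, `1 − |Δdosage|/2`, averaged over loci called in both accessions
(complete-case per pair). Pairs above the threshold (default 0.95) are
duplicates. Pruning is greedy over pairs in descending-IBS order,
removing the worse-ranked member of each still-intact pair — keeping
the better rank preserves the selection intent — followed by a
restoration sweep that re-admits (best rank first) any removed
accession left with no above-threshold conflict among survivors. The
sweep guarantees the result is a *maximal* duplicate-free subset;
without it, chains like A~B, B~C can strand an accession whose only
conflict was itself removed. Greedy-by-rank is not guaranteed to be a
*minimum* removal set on arbitrary conflict graphs, but clone clusters
in practice are isolated pairs or short chains where it is.

Dedup is applied within each collection after truncation;
cross-collection duplicates are allowed. An optional backfill pass
refills freed slots from the saved post-eligibility ranking, skipping
candidates that would re-introduce a duplicate.

## Diversity statistics

**Shannon–Weaver.** Quantitative traits are cut into six equal-width
classes whose boundaries derive from the *entire* collection's observed
range — also when scoring a sub-collection — under a half-open-left
convention (a boundary value belongs to the lower class; the minimum
belongs to class 1). `H' = −Σ p ln p` is normalized by ln(number of
*defined* classes), not realized classes, so a sub-collection that has
lost classes scores lower; 0 is monomorphism, 1 a uniform spread.
Qualitative traits use their descriptor's defined class count.

**Ho / Hs / Fis.** Single-population treatment, per locus with `ñ`
non-missing diploid calls and sample allele frequencies `p̃`:
`Ho` = heterozygote fraction,
`Hs = (ñ/(ñ−1)) (1 − Σ p̃² − Ho/(2ñ))` (Nei–Chesser small-sample
correction), `Fis = 1 − Ho/Hs` where `Hs > 0`. Loci with `ñ < 2` are
excluded from `Hs`/`Fis`. The mean `Fis` is reported both as the mean of
per-locus values and as `1 − mean(Ho)/mean(Hs)`, since reporting
conventions differ between sources. Diversity statistics refuse
mean-imputed matrices: fractional imputed dosages would fabricate
heterozygotes.

**Allele counting.** Distinct observed alleles summed over loci: at a
biallelic locus the alt allele counts when any call is ≥ 1, the ref
allele when any call is ≤ 1. Retention is `100 · subset/reference`
rounded to two decimals. Counts depend on the counting unit, but
retention ratios are unit-free.

**Kappa.** Cohen's Kappa from the 2×2 selected/unselected table of two
collections over a shared universe (the pipeline uses all phenotyped
accessions; configurable, since the natural universe depends on the
bank). Degenerate vectors give NaN.

## Ordination

PCA is an SVD of the centered (optionally unit-variance scaled) matrix;
explained-variance fractions are taken over all components so they sum
to 1, and eigenvector signs follow a deterministic convention (largest
|loading| positive) for cross-platform reproducibility. Molecular PCA
takes the mean-imputed dosage matrix; phenotypic PCA the standardized
per-trait BLUP matrix.

DAPC retains the minimal leading PCs reaching the configured cumulative
variance (default 80%), capped at `n_samples − n_groups − 1` as an
overfitting guard, then fits a linear discriminant (at most
`n_groups − 1` axes) on the retained PC scores with collections as
a-priori groups. Reassignment accuracy is in-sample by design — the
question is how separable the given grouping is, not out-of-sample
prediction — and is therefore benchmarked against a label-permutation
null (add-one p-value) rather than cross-validation. Accessions in
several collections receive a single label by the configuration's theme
order.

## Synthetic germplasm

The generator produces data with the statistical structure the pipeline
assumes, with truth tables for testing:

* **Genotypes.** Two-level Balding–Nichols sampling: ancestral
  frequency `p ~ U(maf_floor, 1 − maf_floor)`, population frequencies
  `~ Beta(p(1−F)/F, (1−p)(1−F)/F)` at divergence `F`, dosages
  `~ Binomial(2, p_pop)`. Defaults: 300 accessions, 2000 loci spread
  over 18 chromosomes, 3 populations, F = 0.10. Clone pairs copy a
  progenitor row and redraw each locus with probability
  `clone_error_rate` (default 0.01) uniformly from the other two dosage
  codes, modelling genotyping discordance between true duplicates. The
  expected IBS of a clone pair is then
  `1 − e·(0.75·P(hom) + 0.5·P(het))`, comfortably above 0.95 for
  e ≤ 0.03, which the suite verifies empirically.
* **Trials.** Effects drawn exactly per the mixed model; default
  variance components (1.0, 0.3, 0.5, 1.0) for (g, b, ge, e) per trait
  — genetic and residual variances of comparable size, moderate G×E,
  smaller block effects, an entry-mean h² around 0.7 that matches
  well-characterized quantitative traits. Unbalance: each accession
  joins each environment independently with probability 0.8 (redrawn if
  an accession loses every environment); records are then deleted
  completely at random at rate 0.05. Defaults: 3 environments × 2
  blocks.
* **Qualitative scores.** A latent class per accession from the
  configured class probabilities; each year's observation equals the
  latent class with probability 0.9, else uniform over the other
  classes. The mode across years recovers the latent class with
  probability ≈ 0.97 for 3 years at fidelity 0.9.

What the generator deliberately does not emulate: linkage
disequilibrium between loci, pedigree structure, genotype–phenotype
coupling (true genetic values are drawn independently of the SNPs),
spatial field trends, informative missingness, and selection across
generations. Passing tests therefore demonstrate correctness of the
estimation and selection machinery under the stated model, not
robustness to those real-data features.

## Problem sizes

The test suite exercises the variance-recovery check at 300 accessions
× 4 environments × 2 blocks over 10 generator seeds, oracle comparisons
at ≤ 20 accessions × 50 loci over 100 seeds, duplicate detection at
2000 loci, and the full pipeline at 100–200 accessions × 500–2000 loci
— sizes chosen so the whole suite and the acceptance script each finish
in a few minutes on a single core while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

* The mixed model has no genomic relationship matrix, pedigree, spatial
  correction or fixed covariates beyond the grand mean.
* Univariate fits per trait; no multivariate REML or genetic
  correlations.
* Mean-dosage imputation is intended only to complete matrices for
  ordination; it is not an LD-aware imputation.
* The VCF writer emits a minimal VCFv4.2 with GT only (reading uses
  cyvcf2 and accepts any biallelic SNP VCF).
* Greedy pruning is heuristic on dense conflict graphs (see above).
* No bootstrap or rarefaction uncertainty on diversity indices.
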