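# germcore

Thematic core collections for crop germplasm banks: BLUP-based,
trait-directed truncated selection, identity-by-state (IBS)
deduplication, and multi-layer diversity validation.

## The problem

A germplasm bank holds thousands of accessions; characterizing all of
them for every breeding objective is impractical. A *thematic core
collection* is a small subset picked for superiority on one theme — root
yield, pest and disease resistance, or root quality in the cassava
setting this package grew out of — rather than for global diversity
coverage. `germcore` implements that construction end to end and then
asks the questions a curator would ask: did selection discard diversity,
and are the collections genuinely distinct?

The workflow is:

1. **Genotypic values.** Multi-environment trial records are highly
   unbalanced, so per trait a linear mixed model

   `y = μ + Zg + Wb + Ti + e`,  with
   `g ~ N(0, σ²_g I)`, `b ~ N(0, σ²_b I)`, `i ~ N(0, σ²_ge I)`,
   `e ~ N(0, σ²_e I)`

   is fitted by EM-REML on Henderson's mixed-model equations; the BLUPs
   ĝ are shrinkage estimates of each accession's genotypic value, and an
   entry-mean broad-sense heritability
   `h² = σ²_g / (σ²_g + σ²_ge/n_env + σ²_e/(n_env·n_rep))` is reported.
   Repeated qualitative scores are collapsed to their mode across years.
2. **Selection.** Per theme, accessions are ranked on each trait's BLUP
   in the stated direction (higher- or lower-better), combined by an
   equal-weight mean of ranks, screened by hard eligibility filters
   (e.g. cyanogenic score < 5, cooking time < 25 min, cream/yellow
   pulp), and truncated to the target size.
3. **Deduplication.** Pairwise IBS
   (`mean over shared loci of 1 − |d_a − d_b|/2` on 0/1/2 dosages) flags
   pairs above 0.95 as clones; the worse-ranked member of each pair is
   removed.
4. **Validation.** Shannon–Weaver indices `H' = −Σ p_i ln p_i`
   (normalized by ln k over six range-based classes for quantitative
   traits), per-locus Ho/Hs/Fis with the Nei–Chesser small-sample
   correction, allele counts and retention percentages versus the entire
   bank, Cohen's Kappa between the collections' selection vectors, and
   PCA plus DAPC (discriminant analysis of principal components) with
   the collections as a-priori groups.

A seeded synthetic-germplasm module generates SNP panels with population
structure and planted clone pairs (two-level Balding–Nichols sampling)
and trial records under the exact mixed model above, so every stage is
testable against known ground truth.

## Worked example

```python
from germcore import (SimulationSpec, simulate_genotypes, simulate_trials,
                      fit_trait, ThemeSpec, build_collection, ibs_matrix,
                      find_duplicate_pairs, prune_duplicates, allele_retention)

spec = SimulationSpec(n_accessions=120, n_loci=1000, clone_pairs=3, seed=7)
genotypes, truth = simulate_genotypes(spec)
records, true_g = simulate_trials(genotypes, spec)

blups = {t: fit_trait(records, t)
         for t in ("root_yield", "dry_matter", "plant_architecture")}
for t, tb in blups.items():
    print(f"{t:>18}: h2 = {tb.h2:.2f}, sigma2_g = {tb.vc.sigma2_g:.2f}")

theme = ThemeSpec(name="CC_Yield",
                  traits={"root_yield": "higher", "dry_matter": "higher",
                          "plant_architecture": "lower"},
                  n_target=25)
initial = build_collection(blups, theme)

kin = ibs_matrix(genotypes)
pairs = find_duplicate_pairs(kin, threshold=0.95)
final = prune_duplicates(initial, pairs)
print("duplicate pairs in the panel:", len(pairs))
print("final members:", final.size)

ret = allele_retention(genotypes, final.members)
print(f"allele retention: {ret['retention_pct']}% "
      f"({ret['subset_count']} of {ret['reference_count']})")
```

prints

```
        root_yield: h2 = 0.76, sigma2_g = 0.99
        dry_matter: h2 = 0.77, sigma2_g = 1.24
plant_architecture: h2 = 0.82, sigma2_g = 1.28
duplicate pairs in the panel: 3
final members: 25
allele retention: 99.4% (1985 of 1997)
```

The REML estimates recover the generating variance (σ²_g = 1) and all
three planted clone pairs are detected; none of them ranked into this
collection's top 25, so pruning removes nobody — a 25-of-120 core still
carries 99.4% of the panel's alleles.

## Command line

The `germcore` console script exposes each stage (`simulate`, `blup`,
`select`, `dedup`, `diversity`, `validate`) and `run` for the whole
pipeline, driven by a YAML config:

```bash
germcore run --config demo.yaml --out run_dir --seed 1
```

Every stage writes plain TSV/JSON artifacts; `run` additionally writes a
manifest with input hashes, the config echo and per-stage counts.

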