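# spehet

Analysis toolkit for **single-parent-expression (SPE) complementation and
heterosis** in biparental backcross populations, built around the maize
B73 × Mo17 intermated-RIL design: RILs are homozygous mosaics of the two
founder genomes, and crossing each RIL back to a founder yields hybrids
with ~50% heterozygosity arranged in founder-specific blocks. The package
covers the whole chain from genotype calls to variance decomposition, and
ships a ground-truthed synthetic-cross generator so every stage is
testable without any sequencing data.

## What it computes

1. **Genome mosaic classification** (`genotype_regions`). Founder panels
   define high-confidence discriminating SNPs (GQ ≥ 10; ≥ 90% and ≥ 3
   calls homozygous for the expected allele on both sides). Each RIL
   genome is split into B73 / Mo17 blocks with a 15-locus sliding window
   (Mo17 window: ≥ 11/15 hom-alt; B73 window: ≥ 12/15 hom-ref), after
   masking third-origin contamination (≥ 10 RIL-specific loci within
   2.5-Mbp gaps, ≥ 5 homozygous). Blocks < 0.5 Mbp apart merge; RILs with
   > 50% masked genome are excluded with their hybrids. Per-gene hybrid
   zygosity and heterozygosity fractions follow.
2. **Activity and SPE calls** (`expression_spe`). Counts are normalized by
   a gene factor (inverse predictive count of a penalized additive
   smoother on GC content and log gene length) times a TMM sample factor.
   A gene is *active* in a genotype when its mean normalized count
   exceeds τ, the 0.25 quantile of nonzero genotype means. An SPE gene is
   active in the hybrid and exactly one parent; backcross SPE patterns
   1–8 record cross, zygosity and active parent.
3. **Heterosis variance decomposition** (`heterosis_model`). Plant-level
   REML mixed models with the nested aeroponic design factors (batch ⊃
   system ⊃ triplet ⊃ row). The full model regresses trait values on
   parental covariates (0.5/0.5 for hybrids under MPH), per-pattern SPE
   counts (slopes γ₁..γ₄), a hybrid intercept φ and a hybrid random
   deviation; the null model drops the SPE covariates. The explained
   fraction of heterotic variance is

       p_Het = 1 − σ²_Het / σ²_G

   with σ²_Het the full-model and σ²_G the null-model hybrid variance.
4. **eQTL mapping** (`eqtl_mapping`). HMM genotype probabilities on a
   1-cM pseudomarker grid (Haldane, RIL-self map expansion 2), Haley–Knott
   regression LOD = (n/2)·log10(RSS₀/RSS₁), per-gene permutation
   thresholds (99.9th percentile of genome-wide maxima), BH-FDR across
   genes at 0.001, peak merging, and cis/trans labels (cis: < 2.5 Mbp from
   the gene start or support interval covering it).
5. **Association and synteny** (`association_synteny`). A simplified
   per-gene TWAS (trait on rescaled expression plus 3 expression PCs,
   Bonferroni 0.05), TSG nomination (TWAS hit + SPE in > 10 hybrids),
   activity-based t-tests, and Fisher tests of synteny between cis- and
   trans-regulated genes.

The `synthetic_data` module generates every input with known truth:
Poisson/Haldane meioses through an intermating pedigree, genotype-call
noise and GQ mixtures, third-origin contamination, negative-binomial
counts driven by a cis/trans regulatory architecture with
allele-dependent silencing, the nested experimental design, and
phenotypes drawn from the heterosis regression model itself.

## Worked example

```python
from spehet.pipeline import RunConfig, run_all
run_all(RunConfig(seed=7, n_rils=15, n_genes=250, n_perm=1000), "run/")
```

writes, among other stage outputs, `run/heterosis_report.json`:

```
"B73xRIL": { "sigma2_het": 0.0674, "sigma2_g": 0.1651, "p_het": 0.592,
             "phi": 1.223, "mean_mph_pct": 21.5, ... }
```

σ²_Het = 0.0674 is the hybrid-deviation variance left after regressing on
the SPE counts, σ²_G = 0.165 the total hybrid variance, so in this
simulated population the SPE counts explain p_Het = 59% of the heterotic
variance of the (synthetic) trait; φ is the mean hybrid deviation from
mid-parent on the trait scale and `mean_mph_pct` the average mid-parent
heterosis of the hybrids in percent. The same directory contains the
classified regions (`regions.bed`), SPE assignments and counts, eQTL
peaks with cis/trans labels, and TWAS/TSG tables.

The same pipeline is available from the shell:

```bash
spehet run-all --seed 7 --out run/
spehet regions --config run/config.json --out run/   # rerun one stage
```

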