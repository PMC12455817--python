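# Methods

This note documents the models, conventions and design choices behind
`spehet`, and what its synthetic-data calibration does and does not show
about real data.

## Coordinates and containers

All genomic coordinates are 1-based closed bp intervals; genetic
positions come from a linear physical→genetic map (cM = Mbp ×
`cm_per_mbp`). The BED writer converts to 0-based half-open on output.
Genotype calls live in dense (sample × locus) int8 matrices with codes
that distinguish homozygous and heterozygous "other" calls (alleles
matching neither founder), because third-origin masking needs the
distinction. VCF v4.2 round-trips these codes with a second ALT allele
emitted only at loci where some sample carries the third allele.

## Synthetic cross generator

The generator is the definition of the study conditions the package is
calibrated against, not a tuning surface.

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to
the chromosome map length in Morgans, positions uniform on the genetic
map, no interference (Haldane). RILs are built through an intermating
pedigree (F1 selfed to a base population, then random mating for the
configured number of generations, default 4) and finished as a doubled
gamete with map expansion factor 2, the standard expansion of
RIL-by-selfing. Residual heterozygosity is idealized to zero; the
genotype-call error rate (default 0.006, matching the ~99.4% observed
homozygosity of real inbred panels) supplies that realism instead. The
default map rate 0.7 cM/Mbp is maize-like (≈1400 cM over ≈2100 Mbp on
the single-meiosis scale); with the pedigree expansion this gives
roughly one breakpoint per 40 Mbp per RIL, the order observed in
intermated B73×Mo17 RILs.

**Third-origin contamination** overwrites random segments (default
log-normal around 3 Mbp) in a configurable fraction of RILs. At a
contaminated locus the third genome carries a novel allele with
probability 0.6 and otherwise happens to share a founder allele — this is
why masking requires a run of specific calls rather than single loci.

**Genotype calls.** Errors flip a call to one of the other two plain
calls; GQ is a two-component mixture (high calls uniform 90–99, a
configurable 5% of calls below 10). The quality filters downstream (GQ ≥ 10 etc.) therefore
have something to act on.

**Expression.** Expected count = baseline (log-normal across genes,
median 100, ln-sd 1) × activity × artifact(GC, log length) × library
factor, with negative-binomial noise (default α = 0.1 for noisy data,
0.05 in the pipeline fixture; α → 0 gives Poisson, and a deterministic
mode returns the expectation itself for exact oracle tests). Activity is
allele-dependent silencing: a silenced gene is inactive in genotypes
homozygous for the silencing allele at its regulatory locus and active
whenever the required (other-founder) allele is present. This is the
generative mechanism of SPE: e.g. a Mo17-silenced gene is off in Mo17,
on in B73 and on in every B73×RIL hybrid. Third-origin alleles do not
activate silenced genes.

**Design and phenotypes.** The nested aeroponic layout (blocks =
replicates, 4 batches per block, 8 systems per batch, 12 rows per
system, triplet = 3 consecutive rows holding a RIL and its two backcross
hybrids, reference triplets with the founders and an F1 per batch) is
randomized per block. Phenotypes are drawn from the same regression the
analysis fits: parents get their per-se effect; hybrids get mid-parent
plus φ plus γ·(SPE counts) plus a hybrid deviation with variance
σ²_Het, all plus nested design random effects and plant residual.
Default variance components (batch 0.3, system 0.2, triplet 0.2, row
0.15, hybrid 0.2, residual 1.0, on a trait scale with parental effects
near 10) give design noise of the same order as the genetic signal. The
helper `gamma_for_target_p_het` solves for the slope vector whose
implied explained-variance fraction hits a requested value given the
realized SPE counts, which is how the recovery experiments fix their
ground truth.

## Region classification

The pipeline follows the published rule set exactly (GQ ≥ 10; founder
rule ≥ 90% and ≥ 3; masking 10 loci / 5 homozygous within 2.5-Mbp gaps;
windows of 15 with ≥ 11 hom-alt / ≥ 12 hom-ref; 0.5-Mbp block merging;
> 50% masked genome excludes a RIL with its hybrids; 95% homozygosity
sample filter, strict "less than"). Two points were genuinely open and
resolved conservatively:

* **Window stepping.** Windows slide by one locus and a window's label
  applies to every locus it covers; a locus is dropped if *any* covering
  window is ambiguous, if covering windows disagree, or if its own call
  conflicts with the window label. This is the strictest reading of
  dropping loci classified differently from their window.
* **Region ends.** Regions span first-to-last member locus with no
  extrapolation; gaps between regions are no-information. Genes belong
  to the region containing their start; genes overlapping differently
  classified regions are no-information (warned).

A consequence worth knowing: every true breakpoint leaves a
no-information gap about two window-widths wide, so *coverage* of the
genome saturates below 100% (≈97–99% at 20–40 loci/Mbp) while the
*accuracy* of assigned length is ≈99.99%. The recovery experiment
reports both; the headline recovery metric is accuracy over assigned
length, which is the quantity the rule set controls.

## Normalization and activity

The artifact smoother is a penalized B-spline additive model (df 8,
cubic, plus explicit intercept) of log(mean count + 0.5) on GC and log
length, with the penalty weight chosen by generalized cross-validation
over a log-spaced grid; the predictive count is the back-transformed
fit, floored at a tiny positive value. Density estimation before the
activity quantile is replaced by the direct empirical quantile (linear
interpolation): the quantile is the operative statistic. TMM uses the
canonical trims (30% on M, 5% on A, split between tails), reference =
sample whose upper-quartile fraction is closest to the mean, precision
weights by the usual delta-method variance, and returns *count
multipliers* renormalized to geometric mean 1 — so an exactly doubled
library gets half the factor of its twin. Activity is strict: a mean
exactly at τ is inactive.

## Heterosis models

All three models are REML linear mixed models fitted by `spehet.mixedlm`:
direct L-BFGS-B maximization of the restricted log-likelihood over log
variance components with analytic gradients, fixed effects profiled by
GLS, convergence tolerance 1e-8, components floored at zero via the log
parameterization (estimates below 1e-7 of the response variance are
reported as exactly zero). The engine is verified against statsmodels
MixedLM and a naive Nelder–Mead optimizer of the same restricted
likelihood.

The full model's fixed effects are: one covariate per parental genotype
(1 on that parent's own observations; 0.5/0.5 on a hybrid's two parents
under MPH, 1/0 at the better parent under BPH), block effects for blocks
2..J with no intercept, four SPE-count slopes (unstandardized gene
counts), and the hybrid dummy z (coefficient φ). Random effects: batch,
system, triplet, row, and the hybrid deviation g·z, switched off for
parents (implemented as a label of −1). The null model drops only the
SPE slopes. p_Het = 1 − σ²_Het/σ²_G may be negative, which means the
null model happened to place less variance on hybrid deviations, not a
negative influence of SPE.

Two interpretation choices: the σ²_Het/σ²_G naming follows the published
table footnote (σ²_Het = full model, σ²_G = null model), which is the
assignment that reproduces the printed coefficients; and the four SPE
covariates get four distinct slopes (a shared-slope option exists),
reading the repeated slope symbol in the printed model as a typo.

Models are fitted on row means by default (`collapse="rows"`): every
covariate is constant within a row, so for balanced rows this is an
exact sufficiency reduction for all non-residual components — σ²_Het,
σ²_G and p_Het are unchanged while the covariance matrix shrinks by the
plants-per-row factor. Plant-level fitting is available by passing
`collapse=None`. Traits "root_tips", "total_root_length" and
"total_root_volume" are analyzed as sqrt(y + 0.5); lateral root density
is untransformed; the variance models operate on the transformed scale.

## eQTL scan

Marker preparation drops individuals with > 19% missing calls and
duplicated individuals, markers with > 60% missing, then thins greedily
to ≥ 1 cM keeping the first marker of each run; pseudomarkers fill every
gap to ≤ 1 cM with physical positions interpolated linearly. The HMM
uses Haldane recombination fractions with the RIL-self transformation
R = 2r/(1+2r), symmetric emission error 0.001, and forward–backward
normalization (probabilities sum to 1 at every position, including
pseudomarkers). The Haley–Knott LOD is computed from the squared
correlation of phenotype and dosage; exact fits are capped at LOD 300;
positions or phenotypes without variance score 0.

Permutation significance reshuffles the expression vector (default
10,000 permutations; the calibration experiments use 1,000), records
genome-wide maxima, takes the 99.9th percentile as the α = 0.001
threshold, and reports adjusted p as the fraction of maxima ≥ the
observed LOD (0 therefore means "below 1/n_perm"). Support intervals are
1.5-LOD drops (the published analysis names only "confidence interval";
the 1.5-LOD drop is this package's convention, as is plateau
tie-breaking to the lowest coordinate and valley-depth peak merging).
BH-FDR across genes uses effective n = total genes + secondary peaks;
same-gene peaks are distinct only if ≥ 25 Mbp apart or on different
chromosomes with mutually exclusive support intervals, otherwise the
shortest-interval (then highest-LOD) peak survives. cis = same
chromosome and (< 2.5 Mbp from the gene start or interval covering it).

The genetic map is taken from the simulator's truth (or a supplied map);
iterative map re-estimation is out of scope, with an optional Haldane
inverse of adjacent recombination fractions where a map must be derived
from data.

## TWAS simplification

The association stage deliberately replaces multi-locus mixed-model
scans with a per-gene linear model (trait on [0,2]-rescaled expression
plus the first three expression PCs, Bonferroni over the genes passing
the 5%-activity filter). Kinship is omitted. Hit lists from this
simplification are not expected to match kinship-aware scans on real
data; within the synthetic cross the calibration shows ~80% power at the
calibrated effect size and controlled family-wise error.

## What the calibration does and does not show

The generator reproduces the statistical structure the analysis assumes:
mosaic homozygous RIL genomes, Mendelian backcross heterozygosity,
allele-dependent silencing, GC/length count artifacts, nested design
noise, and phenotypes generated from the fitted model family itself.
It does not emulate read-level artifacts (mapping bias, duplicate
reads), linkage between regulatory loci and residual population
structure, expression-level variation beyond on/off silencing,
non-additive expression classes, or model misspecification of the
phenotype (the recovery experiments fit the same model family that
generated the data). Passing calibration therefore demonstrates
correctness of the implementations under their own assumptions, not
robustness of the published conclusions to violations of those
assumptions.

## Problem sizes of the shipped experiments

Region recovery: 30 RILs × 3 chromosomes × 40 Mbp at 20 loci/Mbp.
SPE oracle: 10 RILs × 400 genes (8,000 hybrid-gene decisions), exact
agreement required. p_Het recovery: implied truths {0, 0.15, 0.3}, 80
hybrids per replicate, 100 replicates per truth, 4 plants per row with
row-mean collapsing; the mean estimate must sit within ±0.08 of the mean
truth. eQTL null calibration: 500 null genes × 1,000 permutations, 150
individuals, 3 × 60 cM; cis/trans recovery: 100 genes, effect 1.5 SD,
label accuracy ≥ 85% with window-variation flips ≤ 5%.

One estimator caveat: p_Het is a variance ratio, and in a finite sample
the null model can estimate its hybrid variance on the zero boundary
(observed about once in 300 calibration replicates at true p_Het = 0).
In that case there is no heterotic variance to decompose and the
coefficient is reported as undefined (NaN, with a warning) rather than
as an arbitrarily large negative number; the recovery experiment
averages the defined replicates and reports how many were defined.
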