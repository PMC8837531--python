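# Methods

This note documents the statistical procedures implemented in
`p53mutome`, the defaults and their rationale, what the synthetic
generators emulate, and the numerical choices made where the design was
genuinely open.

## Variant classification

**Activity.** Each variant carries transactivation measurements at 8
p53 response elements (WAF1, MDM2, BAX, 14-3-3σ/SFN, AIP1, GADD45,
NOXA, P53R2), in % of wild-type activity. The classifier works on the
arithmetic mean of the 8 values. Bins are half-open with the lower edge
inclusive: LOF `[0,10)`, partial-LOF low `[10,20)`, partial-LOF high
`[20,50)`, retained `[50,∞)`. The convention that exactly 50 %WT is
"retained" keeps the bins disjoint while matching the usual 10–50%
phrasing of the partial-LOF window; the edges are configurable so the
alternative closure can be tested. Values above 100 %WT (super-active
variants) are permitted. Variants lacking any of the 8 activity values
are dropped at load time and counted in the read audit — every activity
statistic requires the full vector.

**Frequency.** With `f_v = count_v / Σ counts`, the hotspot class is
the fixed set of the 10 largest counts (ties broken lexicographically
by protein change); among the rest, very frequent means `f ≥ 0.5%`,
frequent `0.05% ≤ f < 0.5%`, unique a single occurrence, and rare the
remaining low-share multi-occurrence variants. Only the 0.05% boundary
is anchored in the published analysis of this framework; 0.5% is a
default assumption and both are configurable. Variants with count 0
(possible in curated tables after merging) are binned with the unique
class, as they have no frequency share.

**Identity and merging.** Variant identity is the protein change
(e.g. `R175H`); distinct nucleotide changes yielding the same protein
change are merged by summing counts and averaging annotations, since
all statistics are at protein-variant level. Codons are 1-based protein
positions; the DNA binding domain window is 100–300 inclusive.
Cooperativity mutants are codons 180/181 (the E180/R181 intermolecular
salt bridge). "Damaging" is the OR of the three predictor flags (SIFT,
MutationAssessor, PROVEAN), consumed as precomputed annotations.

**Summaries.** Prevalence summaries report per-class proportions,
median, interquartile range and 10–90 percentiles. At the tumor level
each variant contributes with weight equal to its occurrence count;
percentiles are computed on the expanded occurrence vector (linear
interpolation, the numpy default), so tumor-level and variant-level
summaries coincide exactly when all counts are 1.

**Relative fitness score.** RFS (from variant-expression screens;
higher = stronger loss of antiproliferative activity) is binned with an
open intermediate interval: `rfs ≥ 0` LOF-like, `−2 < rfs < 0`
intermediate, `rfs ≤ −2` WT-like. RFS is optional per variant.

## Residual transactivation

Fold changes are always taken against the p53-null condition:
`log2FC_c(g) = log2((mean_c(g)+ε)/(mean_null(g)+ε))` with pseudocount
ε = 1 expression unit by default (common practice for FPKM/TPM-scale
data; configurable). The statistic is scale-invariant when ε is scaled
with the data.

Differential expression uses per-gene Welch t-tests on `log2(x+ε)` with
Benjamini–Hochberg correction across all genes. The published analyses
this package follows specify the *filter* (mean log2FC ≥ 1, corrected
p ≤ 0.05) but not the testing engine; a transparent Welch test keeps
the stage self-contained and the filter thresholds are the contract.
Genes with degenerate variance in both groups receive p = 1. Conditions
with fewer than 2 replicates are refused by all variance-based steps.

A mutant's residual activity over a gene set is the **ratio of
medians** of mutant and WT fold changes, in percent, over the subset of
genes whose WT response exceeds a responsiveness floor (0.25 log2 units
by default) in the scored direction. Activated and repressed targets
are scored separately because their fold changes have opposite signs.
Ratio-of-medians was chosen over median-of-ratios for robustness to
near-zero per-gene WT fold changes; the per-gene alternative is
available behind a config switch. Values below 0% or above 100% are
reported unclamped with an `out_of_range` flag, and
`reduction = 100 − residual` is emitted alongside. If the WT median
over the restricted set is below the floor the set is rejected as
WT-unresponsive rather than scored against an unstable denominator.

Direct target sets are the intersection of the DE-filtered genes with a
ChIP-peak gene list, both consumed as gene sets.

## Gene-set enrichment

Genes are ranked by a pairwise contrast metric, descending, with ties
broken by gene identifier for determinism. The default metric is the
log2 fold change between the two conditions (means + pseudocount); a
signal-to-noise metric with a variance floor is available.

The enrichment score is the signed maximum deviation of the weighted
running sum: in-set genes advance by `|metric|^p` normalized over
in-set genes, others retreat by `1/(N−N_hit)`; `p = 1` by default,
`p = 0` gives the classic unweighted statistic. If all in-set metrics
are zero the hit weights fall back to uniform. `|ES| ≤ 1` always.

**Null model.** Set membership is reassigned uniformly at random with
the set size preserved (gene-label permutation). Phenotype permutation
was rejected by design: with n = 3 replicates per condition it is
degenerate. This is a deviation from default GSEA practice and means
the null does not preserve inter-gene correlation.

**p-values.** When the number of distinct membership assignments is at
most 10,000 the null is enumerated exhaustively and the nominal p is
the exact probability that a random assignment scores at least as
extreme in the observed direction (so a set occupying the top ranks of
a 4-gene list scores p = 1/6, one of six assignments). On the
Monte-Carlo path the nominal p follows the sign-conditional add-one
convention of published GSEA, `p = (1+c)/(1+m)` with `c` the number of
same-sign null scores at least as extreme and `m` the number of
same-sign null scores. The two paths condition differently on the sign
of the null (the exhaustive value is the unconditional directional
probability, roughly the conditional one times the probability of that
sign); the Monte-Carlo convention was chosen because it is calibrated —
its type-I error at nominal 0.05 is ~0.05, which the acceptance checks
measure on null data — whereas an add-one estimator over the *full*
permutation count with a sign-adaptive tail would double the type-I
error. Seeds are mandatory for the Monte-Carlo path.

**NES and FDR.** NES divides ES by the mean magnitude of same-sign null
scores (an error is raised, with guidance to raise `n_perm`, if no
same-sign null exists). FDRq compares the tail fraction of pooled null
NES with the tail fraction of observed NES within each sign class,
clipped to [0,1]; FDRq < 0.25 is the significance rule. With a single
gene set the observed-tail denominator is 1 and FDRq reduces to the
null tail fraction.

## Synthetic data

The generators exist so that every stage has inputs with known truth.
Each generator call uses one RNG stream derived from `(seed, call
tag)`, so adding a call never perturbs another call's output, and fixed
seeds reproduce outputs byte-identically. Truth labels are emitted
separately from analysis inputs.

**Mutome.** Defaults emulate a curated TP53 missense extract: 1209
DNA-binding-domain variants; expected counts follow a Zipf law with
exponent 0.9 scaled to 6000 total occurrences (Poisson-sampled, minimum
1), which puts ~30% of occurrences on the top-10 variants and leaves a
large unique-variant tail. Activity is planted per frequency class via
mixtures over the four activity classes, with truncated-lognormal
within-class distributions; the mixtures and the class-specific LOF
centers (hotspots ~2.6 %WT, very-frequent LOF near the upper LOF edge)
were calibrated once, at design time, to the observed cohort shape:
hotspot median activity ~2.6 %WT, unique-variant median ~75 %WT,
variant-level partial-LOF share ~32%, and strictly decreasing median
activity from unique variants to hotspots. This plants the
frequency–activity anticorrelation (Spearman ρ ≈ −0.45) attributed to
selection for loss-of-transactivation mutants. Per-response-element
noise is Gaussian with sd 3 %WT, truncated at 0. A flat mode
(`class_proportions=...`) draws activity classes iid instead, for
parameter-recovery tests. Predictor flags are damaging with probability
0.95 below 50 %WT activity (0.4 above); RFS is a linear map of latent
activity (−3·activity/100) plus Gaussian noise — enough to reproduce
the qualitative LOF/intermediate/WT-like gradient, not a mechanistic
screen model.

**Expression.** 2000 genes with log-normal baseline (log2 mean 6, sd
1.5, i.e. median ~64 expression units — high enough that the ε = 1
pseudocount does not bias fold-change ratios); 200 activated targets
with WT log2FC ~ Normal(2, 0.5) truncated ≥ 1 and 100 repressed targets
~ Normal(−1.5, 0.5) truncated ≤ −1; 3 replicates per condition with
log-scale replicate noise sd 0.25. Each mutant has a planted residual
fraction α ∈ [0,1]: its target log2FC is α times the WT effect plus
regulatory scatter with sd `0.2·(1−α)` — full at complete LOF and
vanishing as α → 1, so that an α = 1 mutant is statistically
indistinguishable from WT (a constant-sd alternative would make the
target set detectable at α = 1 through its inflated metric variance
alone, contradicting that contract). The default mutant panel spans
α = 0 to 0.79, mirroring the 5–79% residual-transactivation continuum
of the cooperativity-mutant class. Optionally a subset of activated
targets is marked with simulated ChIP peaks for direct-target-set
tests.

**What the generators do not emulate.** Library-size and count-noise
structure of real RNA-seq (no negative-binomial counts, no
mean-variance trend), inter-gene correlation, batch effects, clonal
structure or mutational signatures, tissue fields of curated variant
databases, and the mass-action DNA-binding mechanism of rescued
apoptotic activity. Passing recovery tests therefore demonstrates
correctness of the estimators under the planted model, not performance
on real data.

## Numerical choices and degenerate inputs

* Percentiles use numpy's linear interpolation throughout, on expanded
  occurrence vectors at tumor level.
* Running-sum ties (equal positive and negative extremes) resolve to
  the first extreme encountered.
* Ranking ties break lexicographically by gene identifier.
* All-zero genes have fold change 0 by ε-regularization.
* Empty DE results are allowed (with a warning); empty summaries after
  a filter raise an error naming the filter.
* Exhaustive enumeration replaces sampling whenever `C(N, k) ≤ 10,000`.
* The exact p of an enumerable fixture includes the observed assignment
  in its tail count, so p is never 0.

## Problem sizes used by tests and the acceptance script

Recovery checks use the default generator sizes (1209-variant mutomes;
2000-gene studies with 200-gene target sets, 3 replicates), 20 seeds
per planted α, 100 null draws for type-I calibration at n_perm = 200,
and 300–1000 permutations elsewhere. The full suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

* The residual-transactivation statistic is this package's definition
  (ratio of medians); the originating study did not print its exact
  formula, so absolute residual percentages are comparable within this
  framework, not necessarily to other implementations.
* Gene-label permutation ignores inter-gene correlation; FDRq values on
  strongly co-regulated real sets will be anti-conservative relative to
  phenotype permutation.
* Frequency-class boundaries other than 0.05% are assumptions.
* The Welch/BH DE stage is intentionally simple; for real count data a
  negative-binomial engine is preferable and can be substituted
  upstream of the filter, which is the stable contract.
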