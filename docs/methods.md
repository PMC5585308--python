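# Methods

This note documents the statistical models implemented in `mecmir`, the
design decisions taken where several defensible options existed, and what
the synthetic-data generator does and does not emulate.

## Study design and data model

The pipeline targets a paired laminar design: for each animal, layer II
(LII) and the pooled deep layers (LDeep) of the medial entorhinal cortex
are profiled at one of four postnatal ages (P2, P9, P23, P45). Three
measurement platforms are modelled: miRNA microarrays (log₂-scale Gaussian
after quantile normalization), total RNA-seq (negative-binomial counts),
and TaqMan qPCR Ct values for a stellate-cell vs rest contrast. All
downstream code consumes one container, `ExpressionMatrix` (features ×
samples with per-sample annotation and a scale tag), so every stage is
platform-agnostic after normalization.

Genomic coordinates are 0-based half-open internally; GFF3 input/output is
the only place 1-based inclusive coordinates appear. Inter-locus gaps are
therefore simply `next.start − prev.end`, floored at 0 for overlaps.

## Normalization

* **Presence filter.** A feature is kept if it is present (count > 0, or
  non-missing) in at least half the samples of at least one age × layer
  group. The exact detected-above-background rule used by array
  preprocessing software is vendor-specific; the group-wise presence
  fraction is a standard surrogate and is configurable.
* **Quantile normalization** forces every sample onto the mean empirical
  distribution. Ties within a sample receive the mean of the quantile
  values their positions span, which keeps the transform well-defined on
  discrete data; on tie-free data the output columns are exact
  permutations of one another and the transform is idempotent.
* **TMM.** The reference sample is the one whose upper-quartile count
  fraction is closest to the mean of those fractions. M-values (log-ratios
  of count fractions vs the reference) and A-values are each doubly
  trimmed (30% / 5% by default), the surviving M-values are averaged with
  delta-method inverse-variance weights, and factors are rescaled to
  geometric mean 1 (enforced to 1e−12).
* **log-CPM** is `log2((count + 0.5) / (lib·factor + 1) × 1e6)`; the 0.5
  prior keeps zero counts finite. Note the prior does not scale with
  depth, so depth-invariance holds only where counts dominate the prior.
* **Precision weights** follow the voom recipe in simplified form: fit the
  design per feature, lowess (span 0.5) of √σ̂ against mean log-CPM,
  weight = trend⁻⁴ clipped to [1e−6, 1e6]. The weight is per-feature
  (evaluated at the feature's mean abundance) rather than per-observation;
  with balanced library sizes the difference is second-order. A
  single-feature matrix gets unit weights with a logged warning.
* **ΔCt.** Per sample, the mean Ct over features reliably detected in
  *every* sample is subtracted and the sign flipped, so positive values
  mean higher expression and downstream log-fold-changes read the same way
  as for the other platforms. The reference is the all-feature mean, not
  named endogenous controls; features flagged (Undetermined/Unreliable,
  matched case-insensitively) anywhere are dropped before testing.

## Differential expression

Per feature, (weighted) least squares on a design matrix, then
empirical-Bayes variance moderation: log residual variances are fit by the
method of moments to a scaled-F model, giving prior df d₀ (trigamma
inversion by Newton iteration, tolerance 1e−8, ≤50 iterations; d₀ = ∞ when
the moment equation has no positive solution) and prior variance s₀². The
moderated t uses the posterior variance on df + d₀ degrees of freedom.
Zero-variance features are excluded from moment estimation and reinstated
at s² = s₀². Limits are exact: d₀ = 0 reproduces the ordinary t; d₀ = ∞
gives every feature the shared variance s₀².

Contrasts: the age contrast uses a group-means design over ages (late
(P23/P45) minus early (P2/P9) averages); layer contrasts use one indicator
per animal plus one LII × age column per age, so the within-age layer
effects are single coefficients and the pooled layer contrast is their
average. This fits one variance model across ages rather than per-age
fits. Animals are fixed blocks; no random-effect/duplicate-correlation
machinery is attempted. BH adjustment is the plain step-up procedure,
shared by the enrichment module.

## Co-expression modules (recursive gap thresholding)

DE miRNAs (union of all contrasts at BH < 0.05) are clustered on
d = 1 − Pearson r with average linkage; feature ids are sorted before
linkage so results cannot depend on input order. The dendrogram is cut
recursively: at each subtree, k ∈ {1..max_k} is selected by the gap
statistic — within-cluster dispersion W_k = Σ_r (pairwise distances in
cluster r)/(2 n_r) compared against B = 50 reference datasets drawn
uniformly over the per-sample range of the current submatrix, with the
one-standard-error rule (smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}).
k = 1 emits the subtree as a module; otherwise the cut parts are recursed
into, and parts smaller than `min_size` (default 5) become outliers
(label 0). Reference draws come from a single seeded generator, so the
partition is deterministic given the seed. Module representatives are the
per-sample means of the z-scored member profiles.

The emitted module count is an outcome, never a target: the default
synthetic study plants eight modules, and the recursion typically recovers
exactly eight, but no parameter is tuned to force that number.

## Genomic clusters

A cluster is a maximal chain of ≥2 loci on one chromosome with consecutive
gaps ≤ 10 kb, inclusive at the boundary and strand-agnostic. Association
with module co-membership is tested on all unordered pairs of
module-labelled miRNAs (2×2: same genomic cluster × same module) with a
one-sided Fisher p and the sample odds ratio ad/bc (undefined on a zero
margin). Pairs are not independent, so the Fisher p is descriptive; a
module-label permutation p is the calibrated alternative. The permutation
estimator is the usual conservative (1 + #≥obs)/(1 + B); because the pair
statistic is integer-valued, an optional randomized tie-break is provided
that is exactly uniform under the null and is what the calibration tests
use.

## Target integration

Spearman correlations (average ranks under ties) are computed over the
samples shared by the miRNA and mRNA matrices — under the paired design
the matching key is (animal, layer), with age implied. The
three-requirement filter keeps pairs that are (1) conserved-predicted
(context score strictly below −0.1, aggregated per pair as the minimum
score over sites) or database-validated, (2) both DE in the age contrast
or both DE in the layer contrast, and (3) ρ strictly below −0.5.
"Significantly negatively correlated" is operationalized purely as the ρ
threshold; no separate correlation p-value is applied. Ranked shortlists
additionally require gene median normalized log₂ expression ≥ 5 and DE in
both contrasts, ordered by best context score, then most negative ρ, then
gene id.

The correlation-skew analysis compares conserved-predicted pair
correlations against the control of all predicted pairs (including
non-conserved) with a one-sided Mann–Whitney U (conserved stochastically
smaller). Both sides ≤ 8 observations: exact enumeration of all group
assignments (correct under ties); otherwise the tie-corrected normal
approximation with continuity correction. Three stringency filters can be
stacked on the conserved side, in any order (they commute): context score
below a stricter threshold (default −0.25), miRNAs in the top expression
quartile (boundary ties included), and same-module site fraction ≥ 0.75
(fraction of a gene's predicted targeting miRNAs in its modal module).

## Enrichment

One-sided hypergeometric tests per term after intersecting terms with the
universe (default: all genes expressed after filtering) and removing terms
with more than 2500 universe genes *before* testing; BH over tested terms;
sample OR with the Haldane–Anscombe 0.5 correction when a cell is zero.
Query genes need |LFC| strictly above 0.5 among BH-significant features of
the requested direction. The dot-matrix export caps OR at 12 and −log₁₀ p
at 15 (uncapped values are kept in separate columns). Manual curation of
redundant terms is out of algorithmic scope; a blocklist can be applied by
filtering the GMT before input.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly the structure the pipeline is meant to find:

* **Design**: n animals per age (default 3), each contributing one LII and
  one LDeep sample.
* **miRNAs**: baseline log₂ expression uniform on [4, 12]; eight canonical
  module profile shapes (sharp late increase/decrease, laminar profiles
  with opposing age trends, single-age laminar spikes, LII-specific late
  down-regulation, gradual decline) scaled by 2.0 log₂ with ±20%
  per-feature amplitude jitter, plus N(0, 0.5²) noise.
* **Targets**: 20% of genes are regulated, gene = intercept +
  slope × miRNA + noise with slope = −1 × (0.2 + 1.6·p), p the miRNA's
  abundance percentile, and regulated genes assigned preferentially
  (weight ∝ p²) to abundant miRNAs. This abundance scaling is the
  generator's model of dose-dependent repression and of the poorer
  measurability of weakly expressed miRNAs; it is what makes the
  top-quartile skew filter informative. True pairs get conserved-range
  context scores (uniform on [−0.6, −0.15]); decoy predicted sites are
  concentrated on a pool of unregulated genes (so decoy genes carry
  multiple sites from unrelated modules) with mostly non-conserved scores;
  each true target also gets one same-module, non-conserved extra site, so
  true genes have coherent same-module site profiles.
* **mRNA counts**: negative-binomial (dispersion 0.1) around the
  exponentiated log₂ means with log-normal sequencing depths, exercising
  the TMM/log-CPM/weights path.
* **Loci**: half of each module's miRNAs (configurable) are chained on one
  chromosome with gaps strictly below 10 kb; all other loci are ≥10× the
  maximum gap apart.
* **Ct arm**: two groups × 5 replicates; Ct = 38 − expression + noise;
  planted up-regulated miRNAs get −3 ΔCt in the stellate group; a 5%
  Undetermined flag rate by default.

Ground truth records the planted module map, target pairs with their
realised pre-count correlations, DE sets (features whose exact planted
contrast is at least 1.0 log₂ — a two-fold change; weaker planted shifts
are not counted as "planted DE"), genomic clusters, and each miRNA's
best-scored target. Recovery metrics are computed against pairs that are
recoverable in principle: |ρ| ≥ 0.8 at the planted (pre-count) level and
both members planted-DE in a shared contrast — a filter that requires DE
cannot be charged with missing pairs that were never planted as DE.

The generator does **not** emulate: probe-level array artefacts and
background, GC/length biases or between-sample composition shifts beyond
depth, miRNA isoforms and family cross-hybridisation, batch structure, or
real database noise in target predictions. Passing the recovery tests
therefore shows the chain of methods is implemented correctly and has
power under its own assumptions, not that those assumptions hold in any
given real dataset.

## Problem sizes and numerical choices

Default simulations use 80 miRNAs, 400 genes and 24 samples; calibration
properties use 10–100 seeds and permutation tests use 199–1000
permutations — sizes chosen so the full validation suite completes in a
few minutes while keeping Monte-Carlo error well inside the asserted
margins. Stage-specific child seeds are derived from the run seed via
`numpy.random.SeedSequence`, so adding one stage never perturbs another
stage's stream. Tolerances: TMM geometric mean and ΔCt centering to 1e−12;
oracle agreement for elementary statistics to 1e−8 or better; trigamma
inversion to 1e−8.

## Known limitations

* The per-feature (rather than per-observation) precision weights make the
  voom path approximate for strongly unequal library sizes.
* The pair-level cluster/module association treats pairs as exchangeable
  under permutation but not independent under the Fisher model; only the
  permutation p should be interpreted inferentially.
* The gap-statistic recursion can merge two planted modules in unlucky
  noise realisations (observed in roughly one in ten default-sized
  simulations, where ARI drops to ≈0.86); module counts should be read
  with that variability in mind.
* Exact Mann–Whitney enumeration is limited to ≤8 observations per side
  (C(16,8) = 12,870 assignments); beyond that the tie-corrected normal
  approximation is used, which agrees with the exact p to <0.02 at the
  crossover.
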