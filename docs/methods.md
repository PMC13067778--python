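# Methods

This note documents the statistical procedures implemented in
`heteropattern`, the assumptions behind the synthetic-data generator,
the numerical choices made where the design was genuinely open, and the
limits of what the test suite demonstrates.

## Inheritance-pattern classification

For each molecule and each pooled reciprocal hybrid, four replicate
groups are compared: the pooled F1 replicates, each parent's
replicates, and a *mid-parent pseudo-group* built by averaging
replicate-index-matched parental observations (when the parents'
replicate counts differ, the larger group is subsampled with the root
seed before pairing). A one-way ANOVA across the four groups provides a
pooled error term; pairwise contrasts of F1 against MPV and both
parents follow Fisher's LSD (t-contrasts on the pooled mean squared
error at unadjusted α = 0.05, df = N − 4). When the pooled within-group
variance is zero — the noise-free limit — contrasts degenerate to exact
mean equality, making classification exact by construction.

Patterns are assigned by precedence over mutually exclusive geometric
cases: additive (F1 ≈ MPV, ≠ both parents), dominant (F1 ≈ one parent,
≠ MPV; if F1 ≈ both parents while ≠ MPV, the nearer parent breaks the
tie), partially dominant (F1 strictly inside the open interval between
MPV and the same-side parent, ≠ both), overdominant (F1 at or beyond
the same-side parent, ≠ it), otherwise NA. The *same-side parent* is
the parent lying on the F1's side of the mid-parent pseudo-group mean.
An F1 mean exactly on the same-side parent with a significant MPV
contrast is classified dominant, not overdominant. Case-enumeration
tests confirm that every configuration yields exactly one label.

The partial-dominance degree PD = (F1 − P_m)/(P_f − P_m) uses the
female parent as the reference pole (degree 1 at the female parent, 0
at the male, 0.5 at MPV); the classifier also reports the direction of
each call, so the opposite orientation is recoverable. PD is
affine-invariant in the three levels and undefined for coincident
parents. PD degrees pooled over all calls, split at 0.5, yield the
empirical subtypes (t_low, t_high); empty sides fall back to the
canonical 0.3/0.7 with a warning.

Stages are pooled before classification by default (a per-stage flag
exists); molecules appearing in several hybrids contribute one call per
hybrid.

## Heterosis metrics

BPH is computed on genotype means — replicate means enter the ratio,
not per-replicate ratios, since BPH is a property of genotype-level
expectations. Ties in the parental means break toward the female
parent (inconsequential at a tie: BPH is identical either way). A zero
better-parent mean leaves BPH undefined (NaN, flagged). Replicate-level
uncertainty is available as an optional percentile bootstrap CI.
Mid-parent heterosis (F1 − MPV)/MPV is reported as a convenience.
Heterosis correlation matrices (Pearson or Spearman, two-tailed) mask
pairs with < 3 complete hybrids or constant columns.

## Feature screening

The five-stage cascade is strictly nested; each stage filters the
previous stage's survivors.

1. **Differential features.** Per-feature Welch t-test on log2 levels
   (pseudocount 1) with Benjamini–Hochberg adjustment; survivors need
   |log2FC| ≥ 2 and adjusted p ≤ 1e-4. A two-sample location test on
   log2 values stands behind this stage deliberately: the cascade is
   defined by its thresholds, and the engine is isolated so a
   count-model test can be swapped in.
2. **Two-way ANOVA.** Per-feature fixed-effects genotype × stage ANOVA
   with sequential (type I) sums of squares, genotype entered first
   (order configurable); BH-FDR per effect across features; a feature
   survives only if genotype, stage *and* interaction are significant
   at α = 0.05. Features with empty design cells are skipped.
3. **Specificity exclusion.** Drops features whose only significant
   contrast is parent-vs-parent (no hybrid-vs-parent signal anywhere)
   and features differing between reciprocal F1 partners. The rule is
   isolated in one function because "specific to inbred lines" admits
   several readings; this is the most direct one.
4. **Phenotype correlation.** Pearson correlation of genotype × stage
   mean profiles against the phenotype, keep two-tailed p < 0.05.
   Genotype-mean profiles are used because replicate-level trait and
   omics measurements are generally unpaired.
5. **VIP.** A PLS model (latent-factor count chosen by the adjusted-R²
   scan) predicts the per-hybrid response from the surviving features;
   features with mean VIP across factors ≥ 1 survive.

## PLS predictability

PLS fits use NIPALS (scikit-learn) with autoscaled predictors. The
regression scan caps factors at min(100, n − 2, p) and selects the
highest adjusted R² with k = the latent-factor count as the model
dimension — an intentionally simple adjustment, isolated in one line;
exact parity with any particular statistics package's formula is not a
goal. PLS-DA one-hot encodes classes, uses stratified tenfold CV (fold
count reduced to the smallest class size when needed, assignment
seeded) and reports the best Q² = 1 − PRESS/TSS over ≤ 5 components.

The permutation test statistic is the between-/within-class sum of
squares ratio of the *first-component* scores (the first component is
computed from the SVD of the X'Y cross-covariance, the exact first
NIPALS component); an all-components variant is available behind a
flag. p = (1 + #{permuted ≥ observed})/(1 + n_permutations), so 2000
permutations bound p below by 1/2001. The identity-permutation caveat:
with very small samples a random permutation can reproduce the class
split exactly, so the attainable minimum requires the number of
distinct splits to dwarf the permutation count.

VIP is computed per factor count a as
VIP_j(a) = sqrt(p · Σ_{u≤a} SS_u w²_ju / Σ_{u≤a} SS_u) with SS_u the
response sum of squares explained by component u and w_ju the
normalized x-weights; every column satisfies Σ_j VIP_j² = p exactly,
and screening uses the mean over factor counts.

## Networks

Spearman correlations are computed on all within- and cross-layer
feature pairs over shared samples (≥ 4 required); |ρ| ≥ 0.8 edges,
signs retained. Components are ranked by size; walktrap (walk length 4,
configurable) partitions each component into modules. Module
significance is a permutation score — within-module edge density
against 1000 within-component node-label permutations — documented as
this package's own substitute for an external tool's unspecified test;
modules spanning a whole component are unscored (the permutation is
vacuous). Module levels are plain means of member-feature values;
module predictability reuses the PLS-DA engine.

## Variant analysis

Small-variant keys are (CHROM, POS, REF, ALT, GT) with multi-allelic
records split per ALT and the per-ALT genotype re-expressed against
that allele; genotypes are canonicalized unphased with sorted allele
indices ("1|0" ≡ "0/1"). Reference-equal genotypes (0/0) are not
variants and never enter key sets. Interval keys are (CHROM, POS1,
POS2, TYPE, SIZE), 1-based inclusive; a missing SIZE defaults to
POS2 − POS1 + 1. Pairwise common/unique counts are exact set
operations; genetic distance sums unique keys over the classes in
scope. Heterosis correlations use pooled reciprocal hybrids (one BPH
per parent pair per trait). The quadratic fit is ordinary least
squares with the vertex −b/2a reported when a ≠ 0. Haplotype groups
default to exact profile identity; the heterozygous-vs-homozygous
contrast is a Welch t-test.

## Synthetic-data generator

The generator emulates a full reciprocal diallel: n parents, n(n−1)
hybrids in n(n−1)/2 pooled reciprocal pairs, replicated profiles across
stages, trait tables and paired variant sets.

* **Feature levels.** Base levels are lognormal (median 1000, log-sd
  0.5). Parental means spread around the base either lognormally
  (log-sd 0.25) or with a deterministic relative gap for controlled
  power settings. Each feature draws one pattern from the mixture;
  default mixture: additive 0.40, PD-low 0.15, PD-high 0.15, dominant
  0.08 + 0.08, overdominant 0.06, NA-like (coincident parents) 0.08 —
  additive plus partially dominant effects collectively at 70%, the
  regime reported for rice hybrid omics. The F1 true mean follows the
  pattern formula exactly; the overdominant margin defaults to 1.5× the
  parental gap beyond the same-side parent. Patterns are properties of
  the parent pair: reciprocal hybrids share true means (no
  parent-of-origin effects), matching the pooled-reciprocal analysis.
* **Noise.** Replicates multiply the true mean by lognormal noise with
  a fixed CV (mean exactly 1), keeping abundances positive and making
  noise_cv = 0 a clean exact limit. Optional per-stage and
  genotype × stage multipliers give two-way ANOVA true factors.
* **Traits.** The linear model makes each trait a sparse weighted sum
  of true feature levels plus Gaussian replicate noise (sd = 5% of the
  between-genotype spread by default). The multiplicative model draws
  reciprocal component pairs with a common parental yield, components
  additive in the F1 and yield their product — the configuration in
  which component additivity alone produces non-negative yield
  heterosis (AM-GM, equality iff the parents' components coincide).
* **Variants.** For each accession pair and variant class, a fixed
  number of pair-specific shared keys and per-side private keys are
  drawn at globally unique positions, so pairwise common counts are
  known by construction; in panels with > 2 accessions an accession's
  total unique count accumulates private keys from all its pairs.
* **Screening fixture.** A dedicated generator plants three feature
  classes — strongly phenotype-linked features, "decoy" features
  sharing the group/stage structure but diluted by independent
  per-genotype variation, and pure-noise features — so each cascade
  stage has something to reject and the final sensitivity/precision is
  measurable against truth.

What the generator does *not* emulate: count overdispersion and
library-size artifacts of RNA-seq, batch effects, missing-not-at-random
intensity floors, linkage between variants and expression, or
genotype × environment interactions. Passing tests therefore
demonstrate the correctness and calibration of the statistical
machinery under its stated model, not robustness to every failure mode
of real omics data.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale studies chosen to make the
measured properties statistically decidable: noise-free classification
on 6 parents × 1000 features; mode comparison on a 17-parent diallel
(136 pooled hybrids × 30 features); permutation calibration over 500
null datasets at 200 permutations; variant oracles over 55 accession
pairs × 2000 records; network recovery on 2 × 30 features over 30
samples. All randomness flows from one root seed via
`numpy.random.SeedSequence`.

Noteworthy numerics: zero pooled variance switches contrasts to exact
equality at relative tolerance 1e-12; zero-variance features are
dropped by autoscaling (logged); sum normalization rescales each sample
to the mean raw total (any common constant is equivalent after
autoscaling); missing values beyond 50% in every genotype group drop
the feature, the rest are imputed with half the feature minimum as a
limit-of-detection stand-in.

## Known limitations

* Pattern recovery under noise is bounded by contrast power: with 3+3
  pooled replicates, separating a PD_0.3 molecule from additivity is a
  0.2-gap mean shift, so faithful recovery of PD subtypes needs parent
  separations an order of magnitude above the replicate noise sd.
  At a 4× separation overall label recovery is near 50%, rising above
  90% only near 12×.
* The differential stage is a location test on log2 values, not a
  count model; severely overdispersed counts deserve a dedicated
  engine in front of the cascade.
* Module significance scores are a permutation substitute, not
  comparable to any external tool's p-values.
* Adjusted R² from the latent-factor scan is an in-sample criterion;
  for honest out-of-sample claims use the PLS-DA Q² route or an outer
  CV loop.
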