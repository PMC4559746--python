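# Methods

## Model

The pipeline treats a pathway gene *g* as a candidate drug target and
uses the expression of the target genes *t* of the TFs in *g*'s pathway
unit as the transcriptional readout of *g*'s activity. All expression is
assumed to be on the UPC scale, where values are comparable across genes
and bounded in [0, 1]; this is what licenses a *fixed* region threshold
of 0.5 rather than a per-gene quantile. Values outside [0, 1] (beyond
1e-9) are rejected at load time instead of clamped, because an
out-of-range value almost always means the data were not UPC-normalized
and every downstream region split would then be meaningless.

For each pair the samples of both groups are pooled and split by *g*'s
expression into a low region (≤ 0.5, boundary inclusive) and a high
region (> 0.5). Pooling is deliberate: region membership is a statement
about the pathway gene's activity in a sample, not about the sample's
phenotype. Within each region the target's expression is compared
between groups with a two-sample test and summarized as a signed
P-score; the pair's drug targetability combines the low-region score LP
and high-region score HP.

### The P-score transform

The implemented transform is

    pscore(p) = sign · x / (x + 2),   x = −log10 p

It is continuous and strictly decreasing in p, 0 at p = 1, exactly 0.5
at p = 0.01 (the transform's calibration anchor), and saturates toward 1
as p → 0. The constant 2 is fully determined by the anchor:
g(0.01) = 2/(2 + c) = 0.5 forces c = 2. The sign is +1 when the case
mean in the region exceeds the reference mean, −1 when lower, and the
score is 0 when the means are exactly equal. The transform is a
registry entry (`scoring.TRANSFORMS`), so an alternative bounded,
anchored transform can be swapped in without touching the pipeline; all
recovery and calibration properties in the test suite are
transform-shape-agnostic except the closed-form spot values.

No multiple-testing correction is applied. The scores never pass
through an accept/reject decision — they are combined into a continuous
ranking — so FDR control would only distort the transform's calibration.

### The two-sample test

Welch's two-sided t-test is the default: tumor/normal expression
comparisons routinely violate equal-variance assumptions, and Welch
costs nothing when variances happen to be equal. Student's t and the
Mann-Whitney U test are selectable (`method=`). Degenerate inputs are
given explicit conventions: identical means with zero variance in both
groups → p = 1 (no evidence); unequal means with zero variance → the
p-value is floored at 1e-300 before the log transform, which caps
|P-score| below 1 and avoids infinities. All p-values are clipped into
[1e-300, 1].

A region is testable only with ≥ 2 reference and ≥ 2 case samples.
Untestable regions mark the pair *undefined* and exclude it from
merging and the histogram; imputing LP = 0 instead would
systematically inflate targetability for pathway genes with skewed
expression. This is also why groups must have ≥ 4 samples overall: each
region can then in principle hold 2 per group.

### Targetability and modes

The pair score is `|HP| · (1 − |LP|)`. Both factors live in [0, 1]; the
product is 1 only for a fully abnormal high region with a quiet low
region, 0 whenever HP = 0, strictly increasing in |HP| (for |LP| < 1)
and strictly decreasing in |LP| (for |HP| > 0), and invariant to the
signs of both scores — the *location* of the abnormality matters, not
its direction. The combiner is likewise pluggable
(`targetability.COMBINERS`; a clamped `|HP| − |LP|` difference is
provided as an alternative) because only the qualitative shape, not the
exact functional form, is pinned down by the scientific argument.

Mode classification thresholds |LP| and |HP| at 0.5, i.e. p ≤ 0.01
under the anchor — the only significance level the scoring model
distinguishes: `high_only` (restorable; the good-target mode),
`low_only`, `constitutive`, `normal`, with per-region up/down
directions taken from the score signs.

### Merging and ranking

Per pathway gene the k = max(1, ceil(0.05 · n)) largest pair
targetabilities are averaged. The ceiling plus the floor of 1 keeps
genes with few pairs scoreable; averaging the top slice highlights a
gene's most abnormal-but-restorable targets instead of diluting them
across hundreds of quiet pairs. Ties at the cutoff are broken by the
smaller |LP|, then lexicographic target id, and ranking is dense
(exact ties share a rank) with a secondary sort on gene symbol — both
rules exist purely to make output deterministic and order-independent.

### Robustness

Rank stability is estimated by rerunning the entire pipeline on
stratified subsamples: ceil(fraction · n) samples per group, drawn
without replacement (default fraction 0.8, 100 repeats), which
preserves group balance and keeps both regions populated. All (full
rank, subsample rank) points are pooled over genes × repeats into one
Pearson correlation and one least-squares slope with its t statistic. A
master seed spawns per-repeat seeds through `numpy.random.SeedSequence`,
so reports are bit-reproducible. In the identity limit (fraction = 1)
every subsample equals the full cohort; the pooled x and y vectors are
then identical and r and the slope are reported as exactly 1 (the
closed-form value) rather than through the floating-point sqrt.

## Synthetic cohorts

`synthetic_fixtures.generate` emulates exactly the structure the model
assumes: pathway-gene expression drawn per sample from Uniform(0, 1)
(identical in both groups, so both regions are populated in expectation;
a Beta law can be injected for skewed designs), and target expression

    clip(baseline + effect · direction · active + N(0, noise_sd), 0, 1)

where `active` depends on the planted mode (`none`, `high_only_up`,
`high_only_down`, `low_only`, `constitutive`) and on whether the sample
is a case sample in the relevant region. Defaults — 50 samples per
group, baseline 0.4, effect 0.3, noise sd 0.1, 40 pairs per mode over
10 pathway genes — describe a moderately powered cohort: a 0.3 shift
with ~25 samples per group per region is comfortably but not trivially
detectable at p = 0.01. Pairs are dealt to pathway genes in contiguous
blocks in a fixed mode order, so aligned counts give mode-pure genes
(the design used for rank-recovery checks). Clipping against the [0, 1]
bounds is counted and reported; at the defaults it stays well under 1 %,
so the Gaussian noise model remains honest.

What the generator does **not** emulate: probe-level measurement noise,
batch effects, gene-gene correlation, mixed abnormality modes within
one pair, or imperfect TF→target annotations. Passing tests on these
cohorts therefore demonstrate that the pipeline recovers the signal it
defines under its own assumptions — not that those assumptions hold in
any particular real dataset.

## Problem sizes

The test suite and acceptance checks run the pipeline at desk scale:
cohorts of 100 samples, a few hundred pairs, 100 simulation replicates
for rank recovery, and 3–20 subsampling repeats in the robustness
checks — sizes chosen so the whole suite completes in well under a
minute while keeping Monte-Carlo error small relative to the asserted
margins (the null-calibration check, for instance, uses ≥ 2000 region
tests, putting 3 standard errors at ±0.0067 around the nominal 0.01).

## Known limitations

* The pathway-unit input is a flat gene→TF edge list; no pathway
  topology, edge signs, or cascade logic is modeled. Any pathway
  resource must be flattened to that contract first.
* Region splitting at a single fixed threshold discards within-region
  dose information; a pathway gene whose cohort never crosses 0.5
  yields one empty region and drops out entirely.
* The two regions are tested independently; no interaction model links
  them, and sample sizes per region are random variables of the
  pathway gene's expression distribution.
* P-scores from regions with very different sample counts are compared
  on equal footing; the transform calibrates the p-value, not the power.
* Mode labels inherit the arbitrariness of the single 0.5 (p = 0.01)
  threshold; pairs near the threshold flip modes under resampling even
  when targetability is stable.
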