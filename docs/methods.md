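# Methods

## Design

The pipeline quantifies how tandem-repeat (TR) copy-number polymorphism in
promoter regions relates to downstream gene expression across isolates of
two haploid populations.  Its stages are independent and composable:
promoter extraction and TR discovery, normalized-allele-length (NAL)
genotyping, the AICc-selected regression battery ("knob" scan), switch
tests, Fisher enrichment tests, and expression-noise comparisons.  All
statistics run on plain pandas structures; scipy and statsmodels supply
the distributions, exact tests and Tukey–Kramer machinery.

## Promoters and TR discovery

Promoters are the noncoding bases at most 1000 bp upstream of the
annotated translation start, on the gene's strand (for a minus-strand
gene the window sits at higher genomic coordinates and is
reverse-complemented).  By default the window is truncated at any
overlap with another gene's annotated span — a conservative reading of
"noncoding" that clips at neighbouring gene bodies, not merely CDS —
and genes left with zero noncoding bases are omitted with a warning.
`truncate_at_neighbors=False` keeps full windows.

A tandem repeat is a window of `copies ≥ 2` consecutive units of
`unit ∈ [2, 100]` bp covering ≥ 24 bp whose *conservation* — the
fraction of bases matching the per-column majority consensus of the
stacked units (ties broken alphabetically; N never matches) — is ≥ 0.90.
Units of 2–9 bp are microsatellites, ≥ 10 bp minisatellites;
homopolymers are excluded.

Reporting uses *trimmed maximality*: a window is reported only if no
one-unit extension is both admissible (still ≥ the threshold) and at
least as well conserved, and no one-unit shrink is strictly better
conserved.  This mirrors how mismatch-penalising repeat finders treat
tract boundaries.  Two consequences are deliberate: a pure tract does
not absorb flanking junk merely because the averaged conservation stays
above 0.90 (a pure (AC)₁₂ is reported as 12 copies at conservation 1.0,
not 13 copies at 24/26), and an imperfect *terminal* unit is shed, which
can drop a marginal tract below 24 bp entirely.  A plain
threshold-maximality rule cannot do either: any window containing a pure
(AC)₁₁ plus one junk unit sits at ≥ 22/24 ≈ 0.917 and would always be
reported.

Two further rules keep calls parsimonious.  *Primitivity*: a candidate
whose consensus is an exact tiling of a shorter unit (e.g. a unit-12
consensus `ACACACACACAC`) is rejected — that tract belongs to the
smaller-unit analysis.  *Overlap resolution*: candidates whose units
divide one another and whose spans overlap by ≥ 80% of the shorter span
are the same tract and collapse to the smallest unit (an imperfect
periodic tract read at a multiple of its true unit escapes primitivity
and may pick up a flanking base, so exact span equality is not
required); among the remaining overlapping tracts the longer, then
better-conserved, then leftmost wins.  Output ordering is deterministic.

Conservation comparisons are exact (integer cross-multiplication); the
scan prunes copy counts using the bound that scores grow by at most
`unit` per added copy while the requirement grows by `0.90·unit`, which
is exact, not approximate.

One caveat documented rather than "fixed": *strict* monotonicity in the
conservation threshold ("lowering the threshold never removes a call")
cannot hold under any extension rule tied to the threshold — lowering it
can merge a tract into a longer admissible window.  The test suite
asserts the meaningful form: every call at a stricter threshold is
covered by a same-unit call of at least its length at the looser one.

## NAL genotyping and variance tests

Isolates are haploid; one amplicon length per locus and isolate, missing
allowed.  NAL(l, i) = length(l, i) / min over isolates of length(l, ·),
with the minimum over both populations jointly by default
(`per_population=True` switches).  NAL is scale-free and ≥ 1, which
keeps ln x, √x and 1/x well-defined in the regression battery.  A locus
is *fixed* within a grouping when all non-missing lengths are identical;
a single observation counts as fixed (nothing to regress).

Variance comparisons between populations (allelic, in bp², and
expression, in RPKM²) are two-sided F-tests on unbiased sample
variances: F = larger/smaller, p = 2·min(tails) capped at 1, Bonferroni
threshold α/m.  With α = 0.05, m = 72 microsatellite loci gives
0.000694 and m = 123 expressed genes gives 0.000407.  Zero variance on
both sides is degenerate with p = 1; on one side only, degenerate with
p = 0 (direction recorded).

## The knob battery

Seven OLS mean models of expression on NAL: five volume knobs (linear in
x, ln x, √x, x², 1/x; K = 2 coefficients including intercept), an
optimality knob (quadratic, K = 3) and a tuning knob (cubic, K = 4).
Transforms apply to the predictor, not the response.  Fits use
`numpy.linalg.lstsq`; R² = 1 − RSS/TSS, F = (R²/df₁)/((1−R²)/df₂) with
df₁ = K−1, df₂ = n−K, p from the F upper tail.  A constant response is
defined as null signal (R² = 0, p = 1).  Models are skipped, with the
reason kept, when n < K + 2 (AICc denominator) or the design is
rank-deficient (a cubic needs ≥ 4 distinct x values); a constant x is a
caller error — fixed loci must be excluded first.

Model choice minimises

    AICc = ln(RSS) + 2K + 2K(K+1)/(n − K − 1)

with RSS floored at 1e−12 so exact fits stay finite; exact AICc ties
resolve to smaller K, then fixed model order.  This "published" form is
the default.  It is worth being explicit about its behaviour: because
the log-likelihood term lacks the sample-size multiplier, the penalty
difference between K = 2 and K = 3 at n = 16 (≈ 3.08) can only be
overcome if the quadratic cuts RSS to below ~4.6% of the linear RSS —
impossible whenever the residual share of variance exceeds that, e.g. at
any generative R² ≤ 0.95.  Under this form the winner is therefore
almost always the best-fitting K = 2 transform, and the battery reduces
to choosing among volume shapes.  The `aicc="standard"` variant,
n·ln(RSS/n) + the same penalty, restores the usual trade-off and is the
form under which the model-recovery properties below are meaningful.
Both are exposed; the scan takes `aicc=` end to end.  Note also that the
published form is not scale-invariant in y: rescaling y shifts every
model's AICc by the same constant only within an equal-K family, which
preserves within-K ranking but can in principle affect cross-K selection
only through the floor.

The winner's p-value is reported without selection adjustment (one p per
locus), at nominal p < 0.01 and Bonferroni α/m where m is the number of
comparisons actually analyzed.  Under all-null data the winner-p < 0.01
rate is empirically ≈ 0.013 (published form; ≈ 0.021 standard) — the
selection step inflates the nominal rate, which the calibration test
measures rather than hides.

### Scan bookkeeping

Each locus is evaluated in three groupings: population A, population B,
combined.  A comparison is excluded, not tested, when (1) the locus is
fixed within the grouping, or (2) the gene fails the expression rule.
The default rule (`any_zero`) excludes a grouping in which the gene has
zero RPKM in at least one isolate — the strict reading of "expressed in
all samples" — with `all_zero` as the lenient alternative; genes absent
from the matrix are excluded as `no_expression_data`.  The invariant
`tests + exclusions = loci × 3` holds on any input.  On the study-scale
fixture (143 loci, 28 fixed and 9 unexpressed comparisons planted) this
yields 392 tests and a Bonferroni cutoff of 0.000128.

## Switch tests

Within a grouping, a locus is eligible when 2 or 3 distinct allele
lengths each reach frequency ≥ 0.25 among non-missing calls; isolates
carrying rarer alleles are dropped from the test, not merged, since the
frequency threshold defines the compared classes.  Two classes get a
pooled-variance two-sample t-test (Welch by flag), three a one-way
ANOVA; a class with fewer than two observations flags the result
underpowered with no p.  The Bonferroni divisor defaults to the number
of tests that produced a p-value and is overridable, because the
appropriate family size is genuinely ambiguous in this design.

## Enrichment and noise

Differential expression: per-gene pooled t-test of RPKM between
populations, DE iff p < 0.05.  The DE universe is every gene in the
expression matrix, including all-zero genes.  Enrichment builds 2×2
tables (rows: promoter TR present/absent) and applies the two-sided
Fisher exact test in its minimum-likelihood form — the sum of
hypergeometric probabilities of tables at most as probable as the
observed one (scipy's convention, verified against full enumeration);
the odds ratio is the sample estimate ad/bc.  The never-expressed
outcome is zero RPKM in every isolate.

Noise backgrounds: genomic neighbours are the two nearest genes on each
side of every TR gene in genomic order, "upstream" following the focal
gene's strand, with TR-carrying neighbours dropped; function-matched
backgrounds sample, per independent set, one non-TR gene of the same
functional category per TR gene without replacement (multi-category
genes resolved by a seeded uniform choice).  Per-gene expression
variance is computed across all isolates by default (per-population by
flag) on the raw RPKM² scale, with a log₁₀(v+ε) option.  Groups are
compared by one-way ANOVA with Tukey–Kramer adjusted pairwise
comparisons (statsmodels; unequal group sizes supported).

## Synthetic data generator

The generator emulates the study conditions: 2 populations × 8 haploid
isolates; 143 loci (72 microsatellite units of 2–9 bp, 71 minisatellite
units of 10–30 bp); per locus 3–6 distinct alleles = base + unit ×
copy-offset, every non-fixed locus guaranteed polymorphic in both
populations; a 25-locus subset with popA restricted to two adjacent
alleles (reduced allelic variance); 28 fixed comparisons planted as 2
loci fixed everywhere (3 cells each) + 11 fixed in popA only + 11 in
popB only; 9 unexpressed comparisons planted as 1 gene zeroed in all
isolates (3 cells) + 3 genes zeroed in popA (2 cells each — zeroing one
population necessarily silences the combined grouping too, so exactly 1
unexpressed comparison is unplantable and rejected).

Expression: per gene, a mean curve on NAL from the planted pattern
(volume via a random transform, concave quadratic peaked mid-range,
cubic with roots spread over the range, a step at the median allele for
switch, constant for null), standardised to a structural SD of 20 RPKM
around a baseline of 200, plus normal noise whose SD solves
var(noise) = var(μ)·(1−R²)/R² so the generative R² equals
`effect_size` (default 0.5); null loci use SD 20.  Values are clipped at
zero; the baseline/SD ratio keeps draws ≥ 8 SDs above zero at the
default settings so clipping cannot forge an unexpressed comparison.  A
multiplicative lognormal noise option exists for heavy-tailed realism —
recommended if one pushes `effect_size` below ~0.3, where normal-noise
SD grows large relative to the baseline.  Background genes (default
300) are null.  The toy-genome generator plants repeat tracts with
two-unit anti-periodic flanks (so planted truth is exact) and two kinds
of negative control: tracts two units short of 24 bp, and
low-conservation tracts built by per-column balanced substitution so
every ≥ 24 bp window is provably below 90%.

What the generator does *not* emulate: linkage between loci, read-count
sampling noise (expression is generated at the RPKM level), missing
genotype calls, shared-promoter loci, multi-TR genes, or any real
chromatin context for the noise analysis — so passing tests demonstrate
correctness of the statistical machinery under the stated model, not
biological conclusions about real isolates.

## Numerical and design choices

- Tie-breaks are total: consensus ties alphabetical; AICc ties by
  smaller K then model order; overlap resolution by length,
  conservation, position, unit.  Identical inputs and seeds give
  byte-identical outputs.
- K counts mean-model coefficients including the intercept (2/2/2/2/2/
  3/4).  Counting the error variance too (+1 for every model) shifts
  equal-K families identically but can change cross-K selection; the
  chosen convention reproduces the intended parsimony ordering.
- Pooled-variance t-tests are the default throughout (Welch by flag),
  matching classical point-and-click statistical practice for this
  design.
- The study-scale property checks run at deliberately modest sizes —
  2000 null loci for calibration, 200 identifiable loci per pattern for
  recovery, 100 × 2 kb sequences for the scanner/oracle equivalence —
  chosen to give stable binomial error bars while keeping the whole
  suite fast.
- Model recovery is assessed only on allele designs that can express the
  planted shape (a cubic needs ≥ 4 distinct NAL values; on 3 support
  points every function is exactly a quadratic), and under
  `aicc="standard"` — under the published form higher-K models are
  essentially unselectable at these signal levels (see above).
- Switch-detection power is quoted at a 3-SD mean separation with
  balanced 4/4 classes at the 0.05 level.

## Limitations

- The promoter "noncoding" rule truncates at annotated gene spans only;
  unannotated transcripts are invisible to it.
- The repeat finder reports one call per genomic tract; compound or
  nested repeat structures are resolved to a single parsimonious call
  rather than a hierarchy.
- Winner p-values are not adjusted for model selection; the measured
  null inflation (above) quantifies the cost of that convention.
- Fisher enrichment treats genes as exchangeable; no correction for gene
  length, GC or expression level is attempted.
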