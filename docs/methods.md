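# Methods

## Preprocessing

Single-end MNase-Seq reads start at the 5' end of the ~150 bp protected
fragment, so the inferred nucleosome center is the 5' coordinate +75 bp on
the forward strand and −75 bp on the reverse strand (the mirror rule keeps
the inferred center symmetric about the dyad; the shift is configurable).
Coordinates are 0-based half-open throughout; BED in, BED out.

Single coordinates carrying more reads than a cap (default 5, or a
per-position-multiplicity quantile) are removed entirely, as such exact
pile-ups are characteristic of PCR/sequencing artifacts rather than of
phased nucleosomes, whose reads spread over ±15 bp. Centers are counted in
30 bp bins anchored at coordinate 0 — 30 bp matches the measurement
uncertainty of MNase trimming, and finer grids would not add information.
The corrected track is max(0, signal − control) per bin: a deficit against
naked-DNA digestion carries no positive evidence, only the excess does. No
depth normalization is applied before subtraction by default
(`control_scale` exposes a multiplier for unequal library sizes).

## The eight-model Bayesian scan

Each 150 bp window yields y = (y₁…y₅) with segments S₁ = {y₁,y₂},
S₂ = {y₃}, S₃ = {y₄,y₅}; bins are independent Poisson with one rate per
segment. Segment states:

| state | prior on the rate | intent |
|---|---|---|
| bg | Gamma(α, β), per-chromosome method of moments | genome-wide unpositioned background |
| en | Uniform(0, λ_max), λ_max = chromosome max corrected count | agnostic enrichment |

The prior-to-state binding matters: only with gamma = background and
uniform = enriched does M₁ = (bg, en, bg) mean "flanks look like the
genome-wide background while the center may be arbitrarily enriched";
using one family for both states would make all eight marginals identical.

Method-of-moments fit: with bin mean μ and variance s² (sample variance,
ddof 1), the Poisson–gamma marginal moments give β = μ/(s²−μ), α = μβ.
Without overdispersion (s² ≤ μ) the fit falls back to α = 1, β = 1/μ with
a warning; an all-zero chromosome is skipped (λ_max = 0).

Marginal likelihoods are evaluated in log space through `gammaln` and the
lower incomplete gamma function; for γ(a, x) with x ≪ a, where the
regularized routine underflows, an ascending-series expansion takes over.
The uniform-prior marginal depends on the data only through (n, S), so its
values are precomputed per segment size and total during initialization;
table lookups are bit-identical to direct evaluation because both run the
same code path. The factorial terms Σ −log yᵢ! are common to all eight
models and cancel in the winner, the margin and the Bayes factor.

A window becomes a call only when M₁'s marginal is **strictly** largest;
ties resolve to "not a nucleosome" (conservative). The stride is one bin
(30 bp): counts live on a fixed 30 bp grid, and a finer stride would
require re-binning per offset. An optional offset sweep re-bins at the
five 6 bp phases of the grid for phase-sensitive applications; it is off
by default. Windows whose five bins are all zero are skipped as a fast
path; tests verify this never changes the call set. Overlap resolution is
greedy by descending log BF with ties to the leftmost start; kept calls
have pairwise disjoint central bins.

## Evaluation procedures

**Permutation specificity.** Reads are re-placed uniformly within their
1 kb block (block counts conserved, seeded). Calls surviving permutation
are counted as false positives; true negatives are the remaining candidate
regions, defined as chromosome length / 30 (the granularity of disjoint
central bins — the universe is only used comparatively). The
after-permutation run reuses the hyperparameters and λ_max fitted on the
observed data: the null holds the fitted model constant and randomizes
only the reads. Re-fitting on permuted data instead adapts the background
prior and the enrichment ceiling to the permuted track — in dense regions
the phased signal becomes a uniform excess over the control, and the
re-adapted model flags upper-tail bins as positioned again, which can
erase or even invert the before/after difference.

**Spacing.** For each gene with RPKM > 10, call centers within 1 kb
downstream of the TSS (strand-oriented) get integer indices
kᵢ = round(cᵢ/d) for each candidate spacing d in 120–250 bp (1 bp grid;
duplicate indices invalidate a candidate). Ordinary least squares of
position against index scores each d by its residual sum of squares, and
the best fit's slope is the gene's spacing; equal-RSS ties prefer the
larger d, since an exact array fits both d and d/2 with zero residual and
the sparser numbering is the parsimonious one. Non-consecutive indices
make the estimate tolerant of missed calls. The report is the mean and SD
over genes; the 120–250 bp bounds cover the biologically plausible range
around the ~178–187 bp spacing at active promoters.

**Dinucleotide signature.** For each call, the 150 bp center-spanning
sequence and its reverse complement are pooled (dyad two-fold symmetry)
and per-position {AA,TT} and {GC} dinucleotide frequencies computed
(optionally counting TA with the AT group; non-ACGT positions are excluded
from denominators). D is the mean over the 29 central dinucleotide
positions of f_GC − f_AA/TT. The 95% CI is Wald-type with half-width
√χ²₁,₀.₉₅ · SE ( = 1.96·SE). SE comes from the empirical between-call
variance of the per-call central difference, with the call as the
independent unit. A binomial SE of the form f(1−f)/(2nm) is *not* used: it
would treat all 2nm dinucleotide observations as independent, but the two
strands of one call duplicate each other exactly ({AA,TT} and {GC} are
both closed under reverse complement) and adjacent dinucleotides overlap
by one base (AAA runs), so that formula understates the variance by more
than two-fold and caps achievable CI coverage near 83%. The empirical SE
attains nominal coverage for any sequence-composition model (measured
94.9% over 1000 synthetic replicates; the packaged check uses 200).

## Synthetic data

`simulate_reads` emulates the population picture of phased nucleosomes:
per planted center, Poisson(50) reads displaced by Normal(0, 15 bp)
(highly phased nucleosomes scatter within ~15 bp of the center), plus
uniform background at 0.02 reads/bp, all back-transformed to 5' read
coordinates on random strands by inverting the +75 bp shift. Defaults and
their rationale:

- **100 nucleosomes at 180 bp spacing** on a chromosome with 500 bp
  margins (~19 kb): the array tiles most of the chromosome, mirroring
  chromatin's near-complete nucleosome coverage. Background-prior
  estimation sees mostly array-derived counts, which is what keeps the
  fitted gamma prior informative at these read depths.
- **Planted centers sit mid-bin** on the 30 bp grid. With spacing a
  multiple of the bin size every center shares one grid phase; the
  boundary phase splits each read pile across two bins and measures the
  grid artifact (addressed by the offset sweep), not detector sensitivity.
- **Control depth-matched to the signal library** (background plus
  nucleosome reads per bp): naked-DNA controls are conventionally
  sequenced to the depth of the nucleosome sample. The control shares the
  signal's background read pool, so subtraction is exercised rather than
  vacuous, and is topped up with uniform reads to the matched depth. An
  optional AT-bias multiplier reweights control positions toward AT-rich
  sequence when a genome is supplied, emulating MNase sequence preference.

`simulate_genome` draws iid letters, uniform outside cores; within ±35 bp
of each planted center P(G) = P(C) = (1+δ)/4 and P(A) = P(T) = (1−δ)/4
with δ = `gc_core_effect`. The expected central dinucleotide difference is
then analytic: E[D] = ((1+δ)/4)² − 2((1−δ)/4)² (−3(…)² with TA counted),
which anchors the CI-coverage check. The ±35 bp span covers every
dinucleotide of the 30 bp central window even for calls off by a few bp.

`simulate_spacing_genes` plants per-gene arrays (5 nucleosomes at
offset 90 + 180k from the TSS, jitter sd 10 bp, 20% dropout, alternating
strands, grid-snapped centers like real calls) plus low-RPKM decoy genes
with random centers to exercise the expression filter.

What the generator does **not** emulate: MNase digestion-time effects,
fragment-length variation, mappability gaps, copy-number variation,
sequence-dependent nucleosome affinity beyond the planted GC effect, and
realistic mixtures of fuzzy and phased nucleosomes. Passing tests
demonstrate correctness of the inference machinery and its behavior under
the stated noise model, not performance on real chromatin.

## Problem sizes and numerical choices

The packaged checks run the pipeline at the default ~19 kb chromosome
over 10 seeds, the spacing benchmark at 500 genes, the CI-coverage check
at 200 replicates of 150 cores, and one chromosome-scale scan (50 Mb,
~1.67 M bins, ~6 M reads, completing in seconds thanks to the vectorized
scan and the (n, S) marginal tables). Closed-form marginals are verified
against log-scaled adaptive quadrature of the integrand (relative error
≤ 1e−8 over all one- and two-bin count vectors with entries 0–50); the
quadrature substitutes t = λ^(α+S) when α + S < 1 to remove the
integrable singularity at zero. Floating-point symmetry assertions use
1e−10 absolute tolerance on log marginals, since reversal changes only
summation order.

## Known limitations

- The ~30 bp grid bounds positional resolution; the offset sweep
  mitigates but does not remove phase sensitivity.
- Method-of-moments hyperparameters are estimated from the corrected
  track including enriched bins; on sparsely covered chromosomes
  dominated by isolated spikes the fitted background prior becomes very
  heavy-tailed, which erodes the contrast between M₁ and models with
  enriched flanks.
- Specificity depends on the candidate-universe convention
  (length/30) and is meaningful comparatively, not absolutely.
- Bayes factors are reported raw; no FDR calibration is attempted.
- Occupancy (delocalized) nucleosome scoring is out of scope: the method
  detects well-positioned nucleosomes only.
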