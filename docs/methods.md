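# Methods

This note records the models, conventions and design choices behind each
module, what the synthetic-data generators do and do not emulate, and the
known limitations.

## Coordinates and data model

All internal coordinates are 1-based inclusive (the VCF/GFF convention).
BED and bedGraph inputs are converted at the I/O boundary
(`start_internal = start_bed + 1`). Short-variant identity is the exact
tuple (chrom, pos, ref, alt); multi-allelic VCF records are split into
per-alt calls before any filtering, with each sample's genotype resolved
as the count of that alt allele in its diploid genotype. Genotypes
touching a missing allele (`./1`) map to `missing` — the upstream caller's
evidence for such sites is ambiguous and the pipeline's goal is
specificity. A missing DP is treated as 0, so it fails the depth filter;
same rationale.

## De novo filter cascade

The cascade assumes an inbred cohort: one re-sequenced ancestor and
several derived lines propagated by single-individual descent, so fixed
de novo mutations are homozygous and private to one line.

Stages, in fixed order:

1. **Genotype quality.** Per sample independently: heterozygous genotypes
   → missing; genotypes with depth < 3 → missing. Sites with no remaining
   homozygous-alt sample are dropped. The het purge is per-sample, not
   site-wide: a site het in one line can still be a fixed mutation in
   another, and purging site-wide would sacrifice recall without a
   specificity gain (the sharing partition handles cross-line structure).
2. **Sharing partition.** Sites are classified by which samples carry the
   alt allele. Ancestor-carried → background (ancestral relative to the
   reference genome, inherited cohort-wide); this branch also covers sites
   where a line dropped out, since ancestral evidence alone settles the
   class. Exactly one line, ancestor clean → private (the de novo
   candidates). Two or more lines, ancestor clean → shared subset:
   either a background variant the ancestor call missed or a recurrent
   event, excluded from candidates either way.
3. **Masked/unmasked intersection.** The whole analysis is run against
   both a repeat-masked and an unmasked reference; candidates must appear
   in both, by exact key. This removes masking artefacts without
   re-implementing repeat masking.

A single-line cohort degenerates naturally: every non-ancestral variant is
private, so the same code covers the reference-strain case where the
ancestor itself is the only comparator. Upstream variant-quality
recalibration is out of scope; its effect is represented by an optional
site-level `min_qual` hook (off by default).

Each stage returns a subset of its input and the cascade is idempotent
(both are tested).

## SV consensus

Two callers with complementary evidence (read-pair vs split-read) see the
same event at slightly different coordinates, so calls are matched
leniently: same chromosome and type, |Δstart| ≤ 100 bp (about one read
length), and relative size difference < 50%. The size denominator is the
larger of the two lengths, making the rule symmetric; it is deliberately
*not* transitive, and the pipeline never chains matches. Only the start
breakpoint is windowed (`breakpoint_mode = "start"`); end-coordinate slack
is absorbed by the size criterion. This is one of two defensible readings
of a breakpoint window; the alternative (both breakpoints) is stricter and
not implemented.

The per-line cascade is order-sensitive and fixed: ancestor subtraction
(lenient) → hard filters → high-coverage exclusion → cohort uniqueness →
cross-caller intersection. Hard filters use the printed boundary
semantics: QUAL strictly greater than 90; length and depth bounds
inclusive (50 bp ≤ SVLEN ≤ 1 Mbp; depth presets (25, 150) or (2, 150) per
species). The hard and coverage filters apply to the read-pair branch
only; the split-read branch contributes ancestor- and cohort-filtered
calls to the intersection. High-coverage exclusion drops calls whose
2 kbp window centered on the start (determinism: start, since neither
anchor is canonical) has mean coverage strictly above 100; coverage is a
piecewise-constant track with prefix-sum window queries, positions outside
any run counting 0 and windows truncated at the ends keeping their nominal
length in the denominator.

## Phenotype statistics

The trait is binary per animal; replicates of ≥ 50 scored animals per
strain are pooled before testing. Heterogeneous replicate pairs (Fisher
p < 0.01 within a strain) are logged but still pooled — replicate-level
random effects are out of scope. Confidence intervals are Wilson score
intervals with continuity correction (the closed form matching R's
`prop.test`; verified against it to 1e-9), clamped to [0, 1]; exact
Clopper–Pearson is available behind a flag. These intervals are
conservative: empirical coverage at n = 50, f = 0.3 runs ≈ 95–97%.

All strain pairs in an analysis run form the BH family (the strict upper
triangle of the pair matrix), including the ancestor–MA-parent comparison;
the family choice is recorded here because other conventions exist.
Two-sided Fisher p-values use probability-mass ordering with ties counted,
verified against exhaustive hypergeometric enumeration.

A backcrossed line is MA-like when significantly different from the
ancestor but not from the MA parent (adjusted p, α = 0.05),
ancestor-like in the mirror case, and ambiguous otherwise. Compact letter
displays use insert-and-absorb over the non-significance graph: one group
initially holds all strains; each significant pair splits every group
containing both members (the subgroup keeping the earlier-ordered strain
is emitted first); duplicates and subsets are absorbed; groups are
lettered in order of their earliest member. The display is deterministic
given strain order.

## Interval mapping

A marker is *consistent* when every MA-like line is homozygous MA and
every ancestor-like line homozygous ancestral there. Lines het or missing
at a marker are excluded at that marker only (backcrossed selfed lines are
mostly, not fully, homozygous); ambiguous lines never participate. The
candidate interval is built from the largest run of consecutive consistent
markers (leftmost on ties): it spans from one base past the nearest
violating marker on the left to one base before the nearest on the right,
falling back to chromosome ends. The exclusive-of-violators convention is
a choice; printed interval sizes in this field are Mbp-rounded and do not
pin it down. Intervals are reported in bp and rounded Mbp.

The single-locus check requires exactly one chromosome with a non-empty
interval and perfect class/genotype co-segregation at the markers inside
it. Mutation counts per interval include short variants by position and
large deletions when either breakpoint falls inside.

Mapping resolution is marker-limited: with 8 markers per ~17 Mbp
chromosome the interval floor is the spacing of the markers flanking the
causal site (~2–4 Mbp), which is why serial backcrosses shrink the mean
interval only gradually once flanking markers are already discordant.

## Mutation context

Substitutions are classed as transitions (within purines or within
pyrimidines) or transversions, labelled "X-to-Y". Triplet motifs are the
reference-strand bases at (pos−2, pos−1, pos) — mutant base 3′ — without
pyrimidine collapsing (a collapse option exists but is off by default,
since the motifs of interest are quoted as-is). The 50 bp GC window takes
24 bases left and 25 right of the focal base (the even window cannot be
centered exactly; this split is fixed), truncates at chromosome ends and
excludes Ns from the denominator.

Repeat distances are (d5, d3) to the nearest repeat end/start on either
side, (0, 0) inside a repeat; nested and overlapping repeats are handled
by scanning all left-starting intervals. A side with no repeat reports the
distance to the chromosome end with an `open` flag. Large deletions are
evaluated breakpoint-by-breakpoint as two loci. Repeat enrichment is a
one-df goodness-of-fit χ² of (in, out) counts against the genomic repeat
fraction; at small counts the binomial test is the better oracle and the
χ² result is only directionally reliable (tested as such). Gene-length vs
hit-count correlations are Pearson r over genes, with hits assigned by
containment in either the primary-transcript span or the merged exons.

## Synthetic data: what it emulates, and what it does not

`simulate_ma_cohort` plants background variants (hom-alt in ancestor and
all lines) at a configurable density — default 100/Mbp, an intermediate
between a reference-strain ancestor (near zero) and a divergent wild
isolate (roughly an order of magnitude more) — and line-private de novo
events at Poisson(μ × generations) with μ = 0.4 per genome per generation
over 250 generations (≈ 100 per line), 58% indels, simulated depths
Poisson(20), and an optional het-escape fraction and regional rate
multiplier for hotspot scenarios. Positions are uniform and
collision-free; identical seeds give identical output.

`simulate_backcross_panel` follows the causal-carrying chromosome through
each backcross (the carrier gamete is conditioned on the causal allele, as
in a crossing scheme that tracks the mutant phenotype), then founds each
line by selfing the final hybrid for five single-hermaphrodite
generations. Recombination is Poisson per chromosome per meiosis (default
1.0, approximating the single obligate crossover of nematode chromosomes)
with uniform crossover positions; genotypes are tracked only at marker and
causal loci. Phenotypes are Binomial(n, f_MA) for homozygous-carrier lines
and Binomial(n, f_anc) otherwise — the causal allele acts recessively,
consistent with deriving homozygous lines by selfing before phenotyping.
The generator uses hierarchical random streams (backcross phase, per-line
selfing, per-strain phenotypes), so panels simulated at different
backcross depths from the same seed share their downstream randomness;
comparisons across backcross levels are therefore paired, which is how the
interval-shrinkage trend is measured. Because interval lengths are
quantized by marker spacing, that trend is asserted as non-increasing
adjacent means with a strict overall decrease.

`simulate_sv_callsets` perturbs true SVs per caller with rounded
Normal(0, jitter_sd) breakpoints and ±20% length noise (noise-free when
jitter is 0), drops calls at the per-caller miss rate and adds random
false positives.

What the generators do **not** model: selection during MA propagation
(the design minimizes it), read-level error processes (depths are drawn,
not derived from reads), linkage disequilibrium in background variants,
crossover interference, phenotype-environment interactions, and
mutational spectra beyond the SNP/indel split. Passing tests therefore
demonstrate the correctness and calibration of the *analysis* under the
stated statistical structure, not robustness to artefacts of real
sequencing data.

## Problem sizes

The default verification runs use a six-chromosome 100 Mbp genome;
cohorts of 3 lines × 20 seeds for de novo recovery; 50 backcross panels
per backcross level (200 total) for mapping recovery; 1000 trials for SV
consensus and for null classification calibration; 2000 draws for CI
coverage; 10³-point brute-force oracles for the sequence-context
operations. These sizes put Monte-Carlo error well below every asserted
margin while keeping the full suite under a minute of compute.

## Known limitations

- The mapping interval convention (exclusive of violating markers) and
  the single-breakpoint SV window are each one of two defensible readings;
  both are flagged in config/docstrings.
- The χ² enrichment test is asymptotic; counts with expected cells < 1
  trigger a warning rather than switching tests.
- `read_vcf_minimal` supports GT/DP biallelic-split semantics only — no
  phasing, no breakend notation; SVs enter via the dedicated TSV schema.
- Cross-species transposition of loci for recurrence scans is out of
  scope; recurrence queries take pre-transposed coordinates.
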