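# mamapper

Causal-mutation discovery for mutation-accumulation (MA) line cohorts of
selfing nematodes, built around a binary developmental trait: whether the
vulval precursor cell P3.p divides or fuses with the epidermis.

## The problem

MA lines are propagated through single-individual bottlenecks for hundreds
of generations, so spontaneous mutations fix by drift nearly free of
selection. When an MA line diverges phenotypically from its ancestor, the
responsible mutation is hidden among ~100 fixed de novo mutations — and, in
wild-derived ancestors, among thousands of background variants relative to
the reference genome. `mamapper` implements the computational chain that
goes from joint cohort genotypes to a validated candidate locus:

1. **De novo mutation calling** (`mamapper.denovo`): from a joint cohort
   genotype table (ancestor + derived lines), discard heterozygous and
   under-covered genotypes (fixed mutations in inbred lines are homozygous;
   depth ≥ 3), classify sites by sharing pattern — variants carried by the
   ancestor are background, variants in ≥ 2 lines are suspect, variants
   private to a single line are de novo candidates — and keep only calls
   reproduced in both the repeat-masked and unmasked reference analyses.
2. **Structural-variant consensus** (`mamapper.svmerge`): merge two SV
   callers' outputs under a lenient equivalence rule (same type, start
   positions within 100 bp, relative size difference < 50%), after ancestor
   subtraction, hard filters (QUAL > 90, 50 bp ≤ SVLEN ≤ 1 Mbp, depth
   bounds), exclusion of high-coverage pile-up regions and per-line
   cohort uniqueness.
3. **Phenotype statistics** (`mamapper.phenostats`): pooled division
   frequencies with continuity-corrected Wilson score CIs, all pairwise
   two-sided Fisher exact tests with Benjamini–Hochberg FDR control
   (α = 0.05), classification of backcrossed lines as MA-like (red),
   ancestor-like (blue) or ambiguous (gray), and compact letter displays.
4. **Interval mapping** (`mamapper.mapping`): the candidate interval is the
   minimal region carrying the MA genotype in every MA-like backcrossed
   line and the ancestral genotype in every ancestor-like line, delimited
   by the flanking discordant markers; a single-locus check verifies that
   exactly one chromosome explains the phenotype.
5. **Mutation context** (`mamapper.context`): transition/transversion
   classes, 3-bp motifs (mutant base 3′), GC content in a 50 bp window,
   distance to the nearest repeat on either side, χ² repeat-enrichment
   tests, gene-length vs hit-count correlations and recurrence scans
   against independent mutation catalogues.
6. **Synthetic data** (`mamapper.synthetic`): generators that emulate the
   whole study design — MA cohorts (250 generations, Poisson de novo
   events, shared background variants, simulated read depths), serially
   backcrossed and selfed mapping panels with Poisson recombination and a
   single causal locus of incomplete penetrance, binomial phenotype
   replicates, and jittered dual-caller SV call sets — so every stage is
   testable against planted truth.

## Worked example

Map a simulated backcross panel: 12 lines derived from two backcrosses of a
causal-mutation carrier to its ancestor followed by five generations of
selfing, phenotyped at 100 animals each (division probability 0.7 for
homozygous carriers vs 0.2 otherwise), genotyped at 8 markers per
chromosome plus the candidate mutation:

```python
from mamapper.model import GenomeModel
from mamapper.synthetic import BackcrossSimConfig, simulate_backcross_panel
from mamapper.mapping import map_causal_locus
from mamapper.phenostats import LineClass

genome = GenomeModel(chroms={f"chr{c}": 16_700_000 for c in "I II III IV V X".split()})
causal = ("chrIII", 7_400_000)
markers = [
    (f"m_{c}_{i}", c, 1_500_000 + i * 2_000_000)
    for c in genome.chroms for i in range(8)
] + [("m_causal", *causal)]
cfg = BackcrossSimConfig(
    genome=genome, markers=markers, causal=causal,
    n_backcross=2, n_lines=12, f_anc=0.2, f_MA=0.7, seed=7,
)
genotypes, phenotypes, truth = simulate_backcross_panel(cfg)
result = map_causal_locus(genotypes, phenotypes, "ancestor", "MA_parent", genome)
```

Output:

```
lines classified: 4 MA-like, 8 ancestor-like, 0 ambiguous
candidate interval: chrIII:5,500,001-7,499,999 (2.0 Mbp)
single-locus segregation: True
true causal position inside interval: True
```

The twelve lines split cleanly into red (MA-like) and blue (ancestor-like)
classes by their Fisher/FDR comparisons against the two parents; the
markers discordant with that classification delimit a 2.0 Mbp candidate
interval on chromosome III that contains the planted causal position, and
the phenotype segregates as a single locus.

A thin CLI wraps the same functions for file-based use: `mamapper
validate`, `mamapper denovo`, `mamapper sv-consensus`, `mamapper
phenostats`, `mamapper map`, `mamapper context` (see `mamapper --help`).

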