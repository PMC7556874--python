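"""Minimal-interval mapping of a binary trait from backcrossed lines.

Each backcrossed line is classified as MA-like or ancestor-like from its
phenotype; a marker is *consistent* when every MA-like line is homozygous
for the MA allele and every ancestor-like line homozygous ancestral there.
The candidate interval on a chromosome is the minimal region delimited by
the violating markers flanking the largest run of consecutive consistent
markers (chromosome ends when unflanked).  With a single causal locus the
phenotype must co-segregate with genotype on exactly one chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    GenomeModel,
    Interval,
    MarkerGenotype,
    PhenotypeRecord,
    PipelineError,
    VariantCall,
)
from .phenostats import (
    LineClass,
    classify_backcross_line,
    pairwise_fisher_fdr,
    pool_records,
)


@dataclass
class MappingResult:
    """Outcome of mapping one MA line's causal locus."""

    intervals: dict[str, Optional[Interval]]
    consistent_markers: list[str]
    violating_markers: list[str]
    single_locus_ok: bool
    n_lines_used: int
    classes: dict[str, LineClass] = field(default_factory=dict)
    n_mutations_in_interval: Optional[int] = None

    @property
    def interval(self) -> Optional[Interval]:
        """The unique candidate interval, or None if absent/not unique."""
        found = [iv for iv in self.intervals.values() if iv is not None]
        return found[0] if len(found) == 1 else None


def _genotype_lookup(
    genotypes: Iterable[MarkerGenotype],
) -> dict[tuple[str, str], str]:
    return {(g.line, g.marker): g.allele for g in genotypes}


def marker_consistency(
    marker: str,
    genotypes: Iterable[MarkerGenotype],
    classes: Mapping[str, LineClass],
) -> bool:
    """Does the marker genotype co-segregate with the phenotype classes?

    True iff every MA-like line is homozygous MA and every ancestor-like
    line homozygous ancestral at the marker.  Lines with a het or missing
    genotype there are excluded from this marker's evaluation; ambiguous
    lines never participate.
    """
    lookup = _genotype_lookup(genotypes)
    informative = [
        line
        for line, cls in classes.items()
        if cls is not LineClass.AMBIGUOUS
    ]
    if not informative:
        raise PipelineError("no non-ambiguous line available for mapping")
    ok = True
    for line in informative:
        allele = lookup.get((line, marker), "missing")
        if allele in ("het", "missing"):
            continue
        expected = "MA" if classes[line] is LineClass.MA_LIKE else "ancestral"
        if allele != expected:
            ok = False
    return ok


def candidate_interval(
    chrom: str,
    markers: Sequence[tuple[str, int]],
    genotypes: Iterable[MarkerGenotype],
    classes: Mapping[str, LineClass],
    genome: GenomeModel,
) -> tuple[Optional[Interval], list[str], list[str]]:
    """Minimal candidate interval on one chromosome.

    ``markers`` are (marker id, position) pairs on ``chrom``.  Returns the
    interval (None when no marker is consistent) plus the lists of
    consistent and violating marker ids.  The interval spans from one base
    past the nearest violating marker left of the chosen consistent run to
    one base before the nearest violating marker on the right, falling back
    to the chromosome ends.
    """
    ordered = sorted(markers, key=lambda m: m[1])
    positions = [pos for _, pos in ordered]
    if len(set(positions)) != len(positions):
        raise PipelineError(f"duplicated marker positions on {chrom}")
    genotypes = list(genotypes)
    consistency = [
        marker_consistency(mid, genotypes, classes) for mid, _ in ordered
    ]
    consistent = [mid for (mid, _), ok in zip(ordered, consistency) if ok]
    violating = [mid for (mid, _), ok in zip(ordered, consistency) if not ok]
    if not consistent:
        return None, consistent, violating

    # largest run of consecutive consistent markers; ties -> leftmost
    best_start = best_len = -1
    i = 0
    while i < len(ordered):
        if consistency[i]:
            j = i
            while j < len(ordered) and consistency[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    run_lo, run_hi = best_start, best_start + best_len - 1

    chrom_len = genome.chroms[chrom]
    left = ordered[run_lo - 1][1] + 1 if run_lo > 0 else 1
    right = ordered[run_hi + 1][1] - 1 if run_hi < len(ordered) - 1 else chrom_len
    return Interval(chrom, left, right), consistent, violating


def single_locus_check(
    intervals: Mapping[str, Optional[Interval]],
    genotypes: Iterable[MarkerGenotype],
    classes: Mapping[str, LineClass],
) -> bool:
    """Single-locus segregation: exactly one chromosome yields an interval
    and, within it, phenotype class co-segregates perfectly with genotype
    across all non-ambiguous lines."""
    found = [(c, iv) for c, iv in intervals.items() if iv is not None]
    if len(found) != 1:
        return False
    _, interval = found[0]
    genotypes = list(genotypes)
    inside = {
        g.marker
        for g in genotypes
        if g.chrom == interval.chrom and interval.contains(g.pos)
    }
    return all(marker_consistency(m, genotypes, classes) for m in inside)


def count_mutations_in_interval(
    interval: Interval,
    calls: Iterable[VariantCall],
    sv_calls: Iterable = (),
) -> int:
    """De novo mutations falling inside the interval.

    Short variants count by position; large SVs count if either breakpoint
    lies inside.
    """
    n = sum(
        1
        for c in calls
        if c.chrom == interval.chrom and interval.contains(c.pos)
    )
    for sv in sv_calls:
        if sv.chrom == interval.chrom and (
            interval.contains(sv.start) or interval.contains(sv.end)
        ):
            n += 1
    return n


def map_causal_locus(
    genotypes: Sequence[MarkerGenotype],
    phenotypes: Sequence[PhenotypeRecord],
    ancestor: str,
    ma_parent: str,
    genome: GenomeModel,
    denovo_calls: Sequence[VariantCall] = (),
    sv_calls: Sequence = (),
    alpha: float = 0.05,
) -> MappingResult:
    """End-to-end mapping: classify lines, scan markers, build the interval.

    ``phenotypes`` must include records for the ancestor, the MA parent and
    every genotyped line.  Raises when no line can be classified
    non-ambiguously.
    """
    pooled = pool_records(phenotypes)
    matrix = pairwise_fisher_fdr(pooled, alpha=alpha)
    lines = sorted({g.line for g in genotypes})
    classes = {
        line: classify_backcross_line(line, ancestor, ma_parent, matrix)
        for line in lines
        if line in pooled
    }
    informative = [l for l, c in classes.items() if c is not LineClass.AMBIGUOUS]
    if not informative:
        raise PipelineError("no informative (non-ambiguous) line in the panel")

    by_chrom: dict[str, dict[str, int]] = {}
    for g in genotypes:
        by_chrom.setdefault(g.chrom, {})[g.marker] = g.pos

    intervals: dict[str, Optional[Interval]] = {}
    consistent: list[str] = []
    violating: list[str] = []
    for chrom, marker_pos in sorted(by_chrom.items()):
        iv, cons, viol = candidate_interval(
            chrom, sorted(marker_pos.items(), key=lambda m: m[1]),
            genotypes, classes, genome,
        )
        intervals[chrom] = iv
        consistent.extend(cons)
        violating.extend(viol)

    ok = single_locus_check(intervals, genotypes, classes)
    result = MappingResult(
        intervals=intervals,
        consistent_markers=consistent,
        violating_markers=violating,
        single_locus_ok=ok,
        n_lines_used=len(informative),
        classes=classes,
    )
    if result.interval is not None:
        result.n_mutations_in_interval = count_mutations_in_interval(
            result.interval, denovo_calls, sv_calls
        )
    return result
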