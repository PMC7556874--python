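"""Sequence-context and hotspot analyses of mutation lists.

Covers the descriptive statistics used to ask whether causal mutations sit
in mutation-prone sequence: substitution class and 3-bp motif, GC content in
a 50 bp window, distance to the nearest repeat on either side, repeat
enrichment of a mutation set, gene-length vs hit-count correlation, and
recurrence distance against independent mutation catalogues.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    Gene,
    GenomeModel,
    Interval,
    PipelineError,
    ValidationError,
    VariantCall,
)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class RepeatDistance:
    """Distances (bp) from a locus to the nearest repeat on each side.

    ``d5``/``d3`` are 0 when the locus lies inside a repeat.  When no repeat
    exists on a side, the distance to the chromosome end is reported with
    the corresponding ``open`` flag set.
    """

    d5: int
    d3: int
    in_repeat: bool
    open5: bool = False
    open3: bool = False


def substitution_class(ref_base: str, alt_base: str) -> tuple[str, str]:
    """Classify a single-base substitution and label it "X-to-Y".

    Transitions swap within purines or within pyrimidines; transversions
    cross the two classes.
    """
    for b in (ref_base, alt_base):
        if b not in "ACGT" or len(b) != 1:
            raise ValidationError(f"not a single A/C/G/T base: {b!r}")
    if ref_base == alt_base:
        raise ValidationError("ref and alt bases are identical")
    same_family = (ref_base in PURINES) == (alt_base in PURINES)
    return ("transition" if same_family else "transversion", f"{ref_base}-to-{alt_base}")


def triplet_context(genome: GenomeModel, chrom: str, pos: int) -> str:
    """The 3-bp motif ending at the mutant base: reference-strand bases at
    (pos-2, pos-1, pos).

    Positions too close to the chromosome start, or windows containing
    non-ACGT characters, are reported with ``N`` padding rather than raising.
    """
    if genome.seq is None or chrom not in genome.seq:
        raise ValidationError(f"no sequence available for {chrom}")
    seq = genome.seq[chrom]
    if pos < 1 or pos > len(seq):
        raise ValidationError(f"position {pos} outside {chrom}")
    motif = ""
    for p in (pos - 2, pos - 1, pos):
        base = seq[p - 1] if p >= 1 else "N"
        motif += base if base in "ACGT" else "N"
    return motif


def gc_content_window(
    genome: GenomeModel, chrom: str, pos: int, window: int = 50
) -> float:
    """Percent GC in a ``window``-bp window centered on ``pos``.

    For the even default the window takes floor((w-1)/2) bases left and
    ceil((w-1)/2) bases right of the focal base, truncated at chromosome
    ends; N bases are excluded from the denominator.  Raises if the window
    holds no scorable base.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if genome.seq is None or chrom not in genome.seq:
        raise ValidationError(f"no sequence available for {chrom}")
    seq = genome.seq[chrom]
    lo = max(1, pos - (window - 1) // 2)
    hi = min(len(seq), pos + math.ceil((window - 1) / 2))
    sub = seq[lo - 1 : hi]
    n_gc = sum(1 for b in sub if b in "GC")
    n_ok = sum(1 for b in sub if b in "ACGT")
    if n_ok == 0:
        raise ValidationError(f"window around {chrom}:{pos} holds no A/C/G/T base")
    return 100.0 * n_gc / n_ok


def distance_to_repeats(
    pos: int,
    repeats: Sequence[Interval],
    chrom_length: Optional[int] = None,
) -> RepeatDistance:
    """Distance from one locus to the nearest repeat 5' and 3' of it.

    ``repeats`` must all lie on the locus' chromosome and be sorted by
    start.  A locus inside a repeat reports (0, 0).  Large deletions are
    handled by the caller evaluating each breakpoint as its own locus.
    When no repeat exists on a side, the distance to the chromosome end is
    reported with the matching ``open`` flag set (0 for the 3' side when
    ``chrom_length`` is unknown).
    """
    if not repeats:
        raise PipelineError("no repeat annotated on this chromosome")
    starts = [iv.start for iv in repeats]
    i = bisect.bisect_right(starts, pos)  # repeats[:i] start at or before pos
    # nested/overlapping repeats: any left-starting repeat may still cover pos
    left_end = max((iv.end for iv in repeats[:i]), default=None)
    if left_end is not None and left_end >= pos:
        return RepeatDistance(d5=0, d3=0, in_repeat=True)
    if left_end is not None:
        d5, open5 = pos - left_end, False
    else:
        d5, open5 = pos - 1, True  # distance to chromosome start
    if i < len(repeats):
        d3, open3 = repeats[i].start - pos, False
    else:
        d3 = (chrom_length - pos) if chrom_length is not None else 0
        open3 = True
    return RepeatDistance(d5=d5, d3=d3, in_repeat=False, open5=open5, open3=open3)


def repeat_enrichment_test(
    n_in_repeat: int, n_total: int, repeat_fraction: float
) -> tuple[float, float]:
    """One-df goodness-of-fit chi-square of observed (in, out) counts vs the
    genomic repeat fraction.  Returns (chi2, two-sided p)."""
    if not 0.0 < repeat_fraction < 1.0:
        raise ValidationError("repeat_fraction must lie strictly in (0, 1)")
    if n_total < 1 or not 0 <= n_in_repeat <= n_total:
        raise ValidationError("invalid counts")
    expected = [repeat_fraction * n_total, (1 - repeat_fraction) * n_total]
    if min(expected) < 1:
        import warnings

        warnings.warn("expected cell below 1: chi-square approximation is poor")
    observed = [n_in_repeat, n_total - n_in_repeat]
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return float(chi2), float(p)


def count_hits_per_gene(
    genes: Sequence[Gene],
    positions: Iterable[tuple[str, int]],
    mode: str = "gene",
) -> list[int]:
    """Assign mutations to genes by containment in the selected extent.

    ``mode="gene"`` uses the primary-transcript span; ``mode="exon"`` the
    merged exons.  A mutation may hit several (overlapping) genes.
    """
    if mode not in ("gene", "exon"):
        raise ValidationError(f"unknown mode {mode!r}")
    positions = list(positions)
    hits = []
    for gene in genes:
        n = 0
        for chrom, pos in positions:
            if chrom != gene.chrom:
                continue
            if mode == "gene":
                if gene.tx_start <= pos <= gene.tx_end:
                    n += 1
            else:
                if any(e.contains(pos) for e in gene.exons):
                    n += 1
        hits.append(n)
    return hits


def length_hit_correlation(
    genes: Sequence[Gene],
    hits: Sequence[int],
    mode: str = "gene",
) -> tuple[float, float]:
    """Pearson correlation between gene (or cumulative exon) length and the
    per-gene mutation count.  Returns (r, p)."""
    if len(genes) < 3:
        raise PipelineError("need at least 3 genes")
    if len(hits) != len(genes):
        raise ValidationError("hits and genes differ in length")
    if mode == "gene":
        lengths = [g.gene_length for g in genes]
    elif mode == "exon":
        lengths = [g.exon_length for g in genes]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if len(set(lengths)) == 1 or len(set(hits)) == 1:
        raise PipelineError("zero variance: correlation undefined")
    r, p = stats.pearsonr(lengths, hits)
    return float(r), float(p)


def recurrence_distance(
    chrom: str,
    pos: int,
    reference_positions: Mapping[str, Sequence[int]],
) -> float:
    """Distance (bp) to the nearest mutation of an independent catalogue on
    the same chromosome; ``inf`` when the chromosome holds none."""
    positions = reference_positions.get(chrom)
    if not positions:
        return math.inf
    arr = np.asarray(positions)
    return float(np.min(np.abs(arr - pos)))


def annotate_mutations(
    calls: Sequence[VariantCall],
    genome: GenomeModel,
    window: int = 50,
) -> "pd.DataFrame":
    """Per-mutation context annotation table.

    Columns: chrom, pos, ref, alt, sub_class, type_label, triplet, gc50,
    d5, d3, in_repeat.  SNP-specific columns are NA for indels; repeat
    distances are NA on chromosomes without annotated repeats.
    """
    import pandas as pd

    rows = []
    repeats_by_chrom = {c: genome.repeats_on(c) for c in genome.chroms}
    for call in calls:
        if call.vclass == "SNP":
            sub_class, label = substitution_class(call.ref, call.alt)
            triplet = (
                triplet_context(genome, call.chrom, call.pos)
                if genome.seq
                else None
            )
        else:
            sub_class, label, triplet = "indel", None, None
        gc50 = (
            gc_content_window(genome, call.chrom, call.pos, window)
            if genome.seq
            else None
        )
        reps = repeats_by_chrom.get(call.chrom, [])
        if reps:
            rd = distance_to_repeats(call.pos, reps, genome.chroms.get(call.chrom))
            d5, d3, in_rep = rd.d5, rd.d3, rd.in_repeat
        else:
            d5 = d3 = in_rep = None
        rows.append(
            {
                "chrom": call.chrom,
                "pos": call.pos,
                "ref": call.ref,
                "alt": call.alt,
                "sub_class": sub_class,
                "type_label": label,
                "triplet": triplet,
                "gc50": gc50,
                "d5": d5,
                "d3": d3,
                "in_repeat": in_rep,
            }
        )
    return pd.DataFrame(rows)
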