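"""Core data model shared by every pipeline stage.

All internal coordinates are 1-based and inclusive (the VCF/GFF convention).
BED and bedGraph inputs are converted at the I/O boundary and never leak
0-based coordinates into the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Optional

Genotype = Literal["hom_ref", "het", "hom_alt", "missing"]
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")

MarkerAllele = Literal["ancestral", "MA", "het", "missing"]
MARKER_ALLELES = ("ancestral", "MA", "het", "missing")

SVType = Literal["DEL", "INS", "DUP", "INV", "ITX"]
SV_TYPES = ("DEL", "INS", "DUP", "INV", "ITX")


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PipelineError):
    """An in-memory record violates one of its invariants."""


class ConfigError(PipelineError):
    """A simulation or filter configuration is inconsistent."""


class SampleCall(NamedTuple):
    """Per-sample genotype and read depth at one variant site."""

    gt: Genotype
    dp: int


@dataclass
class VariantCall:
    """One short variant (SNP or short indel) with per-sample genotypes.

    ``vclass`` is derived from the allele lengths: a substitution of a single
    base is a SNP, everything else is an indel.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    samples: dict[str, SampleCall] = field(default_factory=dict)
    vclass: Literal["SNP", "indel"] = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt alleles are identical at {self.chrom}:{self.pos}"
            )
        self.vclass = "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"
        for sample, call in self.samples.items():
            if call.gt not in GENOTYPES:
                raise ValidationError(f"unknown genotype {call.gt!r} for {sample}")
            if call.dp < 0:
                raise ValidationError(f"negative depth for {sample}")

    def key(self) -> tuple[str, int, str, str]:
        """Identity of a short variant: the exact (chrom, pos, ref, alt) tuple."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> set[str]:
        """Samples whose genotype carries the alt allele (het or hom_alt)."""
        return {s for s, c in self.samples.items() if c.gt in ("het", "hom_alt")}


@dataclass
class SVCall:
    """One structural-variant call from a single caller."""

    chrom: str
    start: int
    end: int
    svtype: SVType
    svlen: int
    qual: float = 0.0
    dp: int = 0
    caller: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValidationError(f"unknown SV type {self.svtype!r}")
        if self.start > self.end:
            raise ValidationError(
                f"SV start > end at {self.chrom}:{self.start}-{self.end}"
            )
        if self.svlen < 1:
            raise ValidationError(f"SV length must be >= 1, got {self.svlen}")
        if self.svtype == "DEL" and self.svlen != self.end - self.start + 1:
            raise ValidationError(
                f"deletion at {self.chrom}:{self.start}-{self.end} has "
                f"svlen {self.svlen} != span {self.end - self.start + 1}"
            )


@dataclass(frozen=True)
class PhenotypeRecord:
    """Counts of animals with a divided P3.p cell in one scoring replicate."""

    strain: str
    replicate: str
    n_divided: int
    n_scored: int

    def __post_init__(self) -> None:
        if self.n_scored < 1:
            raise ValidationError(
                f"{self.strain}/{self.replicate}: n_scored must be >= 1"
            )
        if not 0 <= self.n_divided <= self.n_scored:
            raise ValidationError(
                f"{self.strain}/{self.replicate}: n_divided {self.n_divided} "
                f"outside [0, {self.n_scored}]"
            )


@dataclass(frozen=True)
class MarkerGenotype:
    """Genotype of one backcrossed line at one marker position."""

    line: str
    marker: str
    chrom: str
    pos: int
    allele: MarkerAllele

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"marker position must be >= 1, got {self.pos}")
        if self.allele not in MARKER_ALLELES:
            raise ValidationError(f"unknown marker allele {self.allele!r}")


@dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class Gene:
    """A gene model: primary-transcript extent plus its (merged) exons."""

    gene_id: str
    chrom: str
    tx_start: int
    tx_end: int
    exons: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.tx_start <= self.tx_end:
            raise ValidationError(f"gene {self.gene_id}: invalid transcript extent")
        prev_end = 0
        for exon in sorted(self.exons):
            if exon.chrom != self.chrom:
                raise ValidationError(f"gene {self.gene_id}: exon on wrong chromosome")
            if exon.start < self.tx_start or exon.end > self.tx_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon outside transcript extent"
                )
            if exon.start <= prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = exon.end

    @property
    def gene_length(self) -> int:
        """Primary-transcript length: exons + introns + UTRs."""
        return self.tx_end - self.tx_start + 1

    @property
    def exon_length(self) -> int:
        """Cumulative length of the merged exons."""
        return sum(e.length for e in self.exons)


@dataclass
class GenomeModel:
    """Chromosome sizes plus optional sequence, repeat and gene annotation.

    ``seq`` may be omitted for analyses that only need coordinates (the MA
    cohort simulator, interval mapping); sequence-context operations require
    it and raise otherwise.
    """

    chroms: dict[str, int]
    seq: Optional[dict[str, str]] = None
    repeats: list[Interval] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seq is not None:
            for chrom, s in self.seq.items():
                if chrom in self.chroms and len(s) != self.chroms[chrom]:
                    raise ValidationError(
                        f"sequence length of {chrom} ({len(s)}) does not match "
                        f"declared size ({self.chroms[chrom]})"
                    )
        for iv in self.repeats:
            self._check_within(iv)
        for gene in self.genes:
            if gene.chrom not in self.chroms:
                raise ValidationError(f"gene {gene.gene_id} on unknown chromosome")
            if gene.tx_end > self.chroms[gene.chrom]:
                raise ValidationError(f"gene {gene.gene_id} extends past chromosome")

    def _check_within(self, iv: Interval) -> None:
        if iv.chrom not in self.chroms:
            raise ValidationError(f"interval on unknown chromosome {iv.chrom}")
        if iv.end > self.chroms[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past chromosome end"
            )

    @property
    def total_length(self) -> int:
        return sum(self.chroms.values())

    def repeats_on(self, chrom: str) -> list[Interval]:
        return sorted(iv for iv in self.repeats if iv.chrom == chrom)

    def repeat_fraction(self) -> float:
        """Fraction of the genome covered by (merged) repeat intervals."""
        covered = 0
        for chrom in self.chroms:
            last_end = 0
            for iv in self.repeats_on(chrom):
                start = max(iv.start, last_end + 1)
                if iv.end >= start:
                    covered += iv.end - start + 1
                    last_end = iv.end
                else:
                    last_end = max(last_end, iv.end)
        return covered / self.total_length

    def base_at(self, chrom: str, pos: int) -> str:
        if self.seq is None or chrom not in self.seq:
            raise ValidationError(f"no sequence available for {chrom}")
        return self.seq[chrom][pos - 1]
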