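"""Readers and writers for the standard formats the pipeline touches.

VCF is read through :mod:`cyvcf2`; GFF3 gene models through :mod:`gffutils`;
FASTA through Biopython; the simple tabular formats (BED3, phenotype TSV,
marker TSV, SV TSV) through pandas.  Everything is normalized onto the
internal 1-based inclusive data model at this boundary.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .model import (
    Gene,
    GenomeModel,
    Interval,
    MarkerGenotype,
    ParseError,
    PhenotypeRecord,
    SampleCall,
    SVCall,
    ValidationError,
    VariantCall,
)

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ["strain", "replicate", "n_divided", "n_scored"]
MARKER_COLUMNS = ["line", "marker", "chrom", "pos", "allele"]
SV_COLUMNS = ["chrom", "start", "end", "svtype", "svlen", "qual", "dp", "caller"]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _decompose_gt(alleles: Sequence[int], alt_index: int) -> str:
    """Resolve one diploid GT against a single alt allele of a split record.

    ``alleles`` are the two integer allele codes of the VCF genotype (-1 for
    missing).  Any genotype touching a missing allele maps to ``missing``;
    otherwise the genotype is the count of ``alt_index`` alleles.
    """
    a, b = alleles
    if a < 0 or b < 0:
        return "missing"
    n_alt = (a == alt_index) + (b == alt_index)
    return ("hom_ref", "het", "hom_alt")[n_alt]


def read_vcf_minimal(path: str | Path) -> list[VariantCall]:
    """Read a VCF with GT/DP FORMAT fields into per-alt :class:`VariantCall`s.

    Multi-allelic records are split into one call per alt allele, with each
    sample's genotype resolved against that alt alone.  Missing genotypes map
    to ``missing``; a missing DP is treated as 0 (it then fails any depth
    filter downstream).
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # malformed header
        raise ParseError(f"{path}: cannot parse VCF header ({exc})") from exc
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    record_no = 0
    try:
        for variant in vcf:
            record_no += 1
            gts = variant.genotypes  # [[a, b, phased], ...]
            try:
                dps = variant.format("DP")
            except KeyError:
                dps = None
            for alt_index, alt in enumerate(variant.ALT, start=1):
                sample_calls: dict[str, SampleCall] = {}
                for i, sample in enumerate(samples):
                    gt = _decompose_gt(gts[i][:2], alt_index)
                    dp = 0
                    if dps is not None:
                        v = int(dps[i][0])
                        dp = max(v, 0)  # cyvcf2 encodes missing DP as negative
                    sample_calls[sample] = SampleCall(gt, dp)
                calls.append(
                    VariantCall(
                        chrom=variant.CHROM,
                        pos=variant.POS,
                        ref=variant.REF,
                        alt=alt,
                        qual=float(variant.QUAL) if variant.QUAL is not None else 0.0,
                        samples=sample_calls,
                    )
                )
    except ValidationError:
        raise
    except Exception as exc:
        raise ParseError(
            f"{path}: malformed VCF record number {record_no + 1} ({exc})"
        ) from exc
    return calls


_GT_CODE = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def write_vcf_minimal(
    calls: Iterable[VariantCall],
    samples: Sequence[str],
    path: str | Path,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write biallelic VCF v4.2 records with GT and DP for ``samples``."""
    lines = ["##fileformat=VCFv4.2"]
    if contigs:
        for chrom, length in contigs.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    lines.append(header + "".join(f"\t{s}" for s in samples))
    for call in calls:
        fields = [
            call.chrom,
            str(call.pos),
            ".",
            call.ref,
            call.alt,
            f"{call.qual:g}",
            "PASS",
            ".",
            "GT:DP",
        ]
        for sample in samples:
            sc = call.samples.get(sample, SampleCall("missing", 0))
            fields.append(f"{_GT_CODE[sc.gt]}:{sc.dp}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read a BED3+ file (0-based half-open) into 1-based inclusive intervals.

    Records with ``end <= start`` are rejected with a warning rather than
    aborting the whole file.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                warnings.warn(
                    f"{path}: line {lineno}: empty or inverted BED interval skipped"
                )
                continue
            intervals.append(Interval(parts[0], start + 1, end))
    return intervals


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    """Write internal intervals back out as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Tabular formats
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Read a phenotype TSV (strain, replicate, n_divided, n_scored)."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "replicate": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["strain", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (strain, replicate) key "
            f"({row['strain']}, {row['replicate']})"
        )
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PhenotypeRecord(
                    strain=str(row["strain"]),
                    replicate=str(row["replicate"]),
                    n_divided=int(row["n_divided"]),
                    n_scored=int(row["n_scored"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_phenotype_table(records: Iterable[PhenotypeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.strain, r.replicate, r.n_divided, r.n_scored) for r in records],
        columns=PHENOTYPE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> list[MarkerGenotype]:
    """Read a marker genotype TSV (line, marker, chrom, pos, allele)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                MarkerGenotype(
                    line=row["line"],
                    marker=row["marker"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    allele=row["allele"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_marker_table(records: Iterable[MarkerGenotype], path: str | Path) -> None:
    pd.DataFrame(
        [(r.line, r.marker, r.chrom, r.pos, r.allele) for r in records],
        columns=MARKER_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[SVCall]:
    """Read an SV call set TSV (chrom, start, end, svtype, svlen, qual, dp, caller)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "svtype": str, "caller": str})
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for idx, row in df.iterrows():
        try:
            calls.append(
                SVCall(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    svtype=row["svtype"],
                    svlen=int(row["svlen"]),
                    qual=float(row["qual"]),
                    dp=int(row["dp"]),
                    caller=str(row["caller"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx + 2}: {exc}") from exc
    return calls


def write_sv_table(calls: Iterable[SVCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.svtype, c.svlen, c.qual, c.dp, c.caller)
            for c in calls
        ],
        columns=SV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta_genome(
    path: str | Path,
    repeats: Optional[list[Interval]] = None,
    genes: Optional[list[Gene]] = None,
) -> GenomeModel:
    """Load a genome FASTA into a :class:`GenomeModel` with sequence attached."""
    seq = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seq:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeModel(
        chroms={c: len(s) for c, s in seq.items()},
        seq=seq,
        repeats=repeats or [],
        genes=genes or [],
    )


def write_fasta_genome(genome: GenomeModel, path: str | Path, width: int = 70) -> None:
    if genome.seq is None:
        raise ValidationError("genome has no sequence to write")
    with open(path, "w") as fh:
        for chrom, s in genome.seq.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    merged: list[Interval] = []
    for iv in sorted(ivs):
        if merged and iv.start <= merged[-1].end + 1 and iv.chrom == merged[-1].chrom:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def read_gff_genes(path: str | Path) -> list[Gene]:
    """Read gene models from GFF3: exon features grouped under their gene.

    Exons of alternative isoforms are merged so each gene carries a set of
    non-overlapping exon intervals; the transcript extent is the gene
    feature's own span.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[Gene] = []
    for feat in db.features_of_type("gene"):
        exons = [
            Interval(e.seqid, e.start, e.end)
            for e in db.children(feat, featuretype="exon")
        ]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            Gene(
                gene_id=gene_id,
                chrom=feat.seqid,
                tx_start=feat.start,
                tx_end=feat.end,
                exons=_merge_intervals(exons),
            )
        )
    return genes
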