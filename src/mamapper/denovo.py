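"""Specificity-first identification of line-private de novo mutations.

MA lines are propagated by constant inbreeding, so fixed de novo mutations
are expected homozygous and private to a single line.  The filter cascade
therefore (1) discards heterozygous genotypes and under-covered genotypes,
(2) partitions the remaining alt-bearing sites by sharing pattern across the
cohort — ancestral background vs shared-subset vs line-private — and
(3) intersects the candidate lists produced from repeat-masked and unmasked
reference analyses, keeping only calls found in both.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .model import PipelineError, SampleCall, ValidationError, VariantCall

VariantKey = tuple[str, int, str, str]


@dataclass
class CohortGenotypes:
    """Joint genotype table of one ancestor and its derived MA lines."""

    ancestor: str
    lines: list[str]
    calls: list[VariantCall]

    def __post_init__(self) -> None:
        required = {self.ancestor, *self.lines}
        for call in self.calls:
            missing = required - set(call.samples)
            if missing:
                raise ValidationError(
                    f"call at {call.chrom}:{call.pos} lacks genotypes for "
                    f"{sorted(missing)}"
                )

    @property
    def samples(self) -> list[str]:
        return [self.ancestor, *self.lines]


def filter_genotype_quality(
    cohort: CohortGenotypes,
    min_dp: int = 3,
    min_qual: Optional[float] = None,
) -> CohortGenotypes:
    """Mask heterozygous and under-covered genotypes; drop empty sites.

    Per sample independently: het genotypes become missing (fixed mutations
    in an inbred line should be homozygous), and genotypes with dp < min_dp
    become missing.  A site survives only if at least one cohort sample still
    carries a non-reference genotype.  ``min_qual`` is an optional site-level
    quality hook standing in for an upstream recalibration threshold
    (default: off).
    """
    filtered: list[VariantCall] = []
    for call in cohort.calls:
        if min_qual is not None and call.qual <= min_qual:
            continue
        new_samples: dict[str, SampleCall] = {}
        for sample, sc in call.samples.items():
            gt = sc.gt
            if gt == "het" or sc.dp < min_dp:
                gt = "missing"
            new_samples[sample] = SampleCall(gt, sc.dp)
        if any(sc.gt == "hom_alt" for sc in new_samples.values()):
            filtered.append(replace(call, samples=new_samples))
    return CohortGenotypes(cohort.ancestor, list(cohort.lines), filtered)


def partition_by_sharing(
    cohort: CohortGenotypes,
) -> tuple[dict[str, list[VariantCall]], list[VariantCall], list[VariantCall]]:
    """Classify each alt-bearing site by its sharing pattern in the cohort.

    Returns ``(private, shared_subset, background)``:

    * private — alt carried by exactly one MA line and not by the ancestor:
      the trustworthy de novo candidates;
    * shared_subset — alt in two or more lines but not the ancestor: either
      a background variant the ancestor call missed or a putative hotspot,
      excluded from de novo candidates either way;
    * background — alt carried by the ancestor (ancestral allele relative to
      the reference genome, inherited cohort-wide).
    """
    private: dict[str, list[VariantCall]] = {line: [] for line in cohort.lines}
    shared_subset: list[VariantCall] = []
    background: list[VariantCall] = []
    for call in cohort.calls:
        carriers = call.carriers()
        if not carriers:
            continue
        if cohort.ancestor in carriers:
            background.append(call)
        elif len(carriers) == 1:
            private[next(iter(carriers))].append(call)
        else:
            shared_subset.append(call)
    return private, shared_subset, background


def intersect_masked_unmasked(
    calls_masked: dict[str, list[VariantCall]],
    calls_unmasked: dict[str, list[VariantCall]],
) -> dict[str, list[VariantCall]]:
    """Keep, per line, only candidates called in both reference analyses.

    Identity is the exact (chrom, pos, ref, alt) tuple; the representative
    call is taken from the masked-reference analysis.
    """
    out: dict[str, list[VariantCall]] = {}
    for line in calls_masked:
        unmasked_keys = {c.key() for c in calls_unmasked.get(line, [])}
        out[line] = [c for c in calls_masked[line] if c.key() in unmasked_keys]
    return out


def call_denovo(
    cohort_masked: CohortGenotypes,
    cohort_unmasked: CohortGenotypes,
    min_dp: int = 3,
    min_qual: Optional[float] = None,
) -> dict[str, list[VariantCall]]:
    """Full de novo cascade over the masked/unmasked cohort pair.

    Composition: genotype-quality filter -> sharing partition -> exact-key
    intersection of the two analyses, returning the line-private class only,
    sorted by (chrom, pos).
    """
    if set(cohort_masked.samples) != set(cohort_unmasked.samples):
        raise PipelineError(
            "masked and unmasked cohorts carry different sample sets"
        )
    private_m, _, _ = partition_by_sharing(
        filter_genotype_quality(cohort_masked, min_dp=min_dp, min_qual=min_qual)
    )
    private_u, _, _ = partition_by_sharing(
        filter_genotype_quality(cohort_unmasked, min_dp=min_dp, min_qual=min_qual)
    )
    result = intersect_masked_unmasked(private_m, private_u)
    for line in result:
        result[line].sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return result
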