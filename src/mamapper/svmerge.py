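"""Consensus structural-variant discovery from two callers' call sets.

SV callers locate breakpoints imprecisely, so calls are matched with a
lenient equivalence rule — same chromosome and type, start positions within
a fixed window (100 bp, about one read length), and relative size difference
below 50% — rather than by exact coordinates.  The consensus pipeline
subtracts ancestor calls, applies hard quality/length/depth filters,
excludes calls in abnormally high-coverage regions (collapsed repeats),
enforces per-line uniqueness within the cohort, and finally intersects the
two callers' surviving call sets.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import ConfigError, PipelineError, SVCall


@dataclass
class SVFilterConfig:
    """Thresholds of the SV consensus pipeline.

    ``dp_range`` is a species preset: (25, 150) for a deeply homogeneous
    coverage profile, (2, 150) for a more dispersed one.  ``breakpoint_mode``
    records the interpretation of the matching window: only ``"start"``
    (|delta start| <= window) is implemented; end-coordinate slack is
    absorbed by the 50% size criterion.
    """

    min_qual: float = 90.0
    min_svlen: int = 50
    max_svlen: int = 1_000_000
    dp_range: tuple[int, int] = (25, 150)
    window: int = 100
    max_size_diff: float = 0.5
    cov_window: int = 2000
    cov_threshold: float = 100.0
    breakpoint_mode: str = "start"

    def __post_init__(self) -> None:
        if self.min_svlen > self.max_svlen:
            raise ConfigError("min_svlen must be <= max_svlen")
        if not 0.0 < self.max_size_diff < 1.0:
            raise ConfigError("max_size_diff must lie in (0, 1)")
        if self.breakpoint_mode != "start":
            raise ConfigError("only breakpoint_mode='start' is implemented")

    @classmethod
    def for_species(cls, species: str, **kwargs) -> "SVFilterConfig":
        presets = {"elegans": (25, 150), "briggsae": (2, 150)}
        if species not in presets:
            raise ConfigError(f"unknown species preset {species!r}")
        return cls(dp_range=presets[species], **kwargs)


def sv_equivalent(a: SVCall, b: SVCall, cfg: SVFilterConfig) -> bool:
    """Lenient identity of two SV calls.

    True iff same chromosome and type, |a.start - b.start| <= window, and
    the relative size difference (denominator: the larger length) is below
    ``max_size_diff``.  Symmetric by construction but not transitive: a
    chain a~b~c does not imply a~c.
    """
    if a.chrom != b.chrom or a.svtype != b.svtype:
        return False
    if abs(a.start - b.start) > cfg.window:
        return False
    return abs(a.svlen - b.svlen) / max(a.svlen, b.svlen) < cfg.max_size_diff


class _SVIndex:
    """Calls grouped by (chrom, svtype) and sorted by start for window lookup."""

    def __init__(self, calls: Iterable[SVCall]):
        self.groups: dict[tuple[str, str], tuple[list[int], list[SVCall]]] = {}
        buckets: dict[tuple[str, str], list[SVCall]] = {}
        for c in calls:
            buckets.setdefault((c.chrom, c.svtype), []).append(c)
        for key, group in buckets.items():
            group.sort(key=lambda c: c.start)
            self.groups[key] = ([c.start for c in group], group)

    def has_equivalent(self, call: SVCall, cfg: SVFilterConfig) -> bool:
        entry = self.groups.get((call.chrom, call.svtype))
        if entry is None:
            return False
        starts, group = entry
        lo = bisect.bisect_left(starts, call.start - cfg.window)
        hi = bisect.bisect_right(starts, call.start + cfg.window)
        return any(sv_equivalent(call, group[i], cfg) for i in range(lo, hi))


def subtract_callset(
    calls: Sequence[SVCall],
    reference_calls: Sequence[SVCall],
    cfg: SVFilterConfig,
) -> list[SVCall]:
    """Remove every call with a lenient equivalent in ``reference_calls``."""
    index = _SVIndex(reference_calls)
    return [c for c in calls if not index.has_equivalent(c, cfg)]


def apply_sv_hard_filters(
    calls: Sequence[SVCall], cfg: SVFilterConfig
) -> list[SVCall]:
    """Hard heuristic filters: QUAL strictly above threshold, inclusive
    length and depth bounds."""
    lo_dp, hi_dp = cfg.dp_range
    return [
        c
        for c in calls
        if c.qual > cfg.min_qual
        and cfg.min_svlen <= c.svlen <= cfg.max_svlen
        and lo_dp <= c.dp <= hi_dp
    ]


class CoverageTrack:
    """Piecewise-constant per-base coverage, queryable for window means.

    Built from bedGraph-style runs (1-based inclusive internally); positions
    not covered by any run count as coverage 0.
    """

    def __init__(self, runs: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in runs.items():
            segs = sorted(segs)
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=float)
            if np.any(starts[1:] <= ends[:-1]):
                raise ConfigError(f"overlapping coverage runs on {chrom}")
            # cumulative coverage mass up to the end of each run
            mass = np.concatenate([[0.0], np.cumsum((ends - starts + 1) * values)])
            self._chrom[chrom] = (starts, ends, mass)

    @classmethod
    def flat(cls, chroms: Mapping[str, int], value: float) -> "CoverageTrack":
        return cls({c: [(1, length, value)] for c, length in chroms.items()})

    @classmethod
    def from_bedgraph(cls, path) -> "CoverageTrack":
        runs: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split()[:4]
                runs.setdefault(chrom, []).append(
                    (int(start) + 1, int(end), float(value))
                )
        return cls(runs)

    def _mass_before(self, chrom: str, pos: int) -> float:
        """Total coverage over positions [1, pos]."""
        starts, ends, mass = self._chrom[chrom]
        i = int(np.searchsorted(ends, pos, side="left"))
        total = float(mass[i])
        if i < len(starts) and starts[i] <= pos:
            value = (mass[i + 1] - mass[i]) / (ends[i] - starts[i] + 1)
            total += (pos - starts[i] + 1) * value
        return total

    def window_mean(self, chrom: str, center: int, window: int) -> float:
        """Mean coverage over the fixed-length window centered on ``center``;
        positions outside the covered range contribute 0."""
        if chrom not in self._chrom:
            raise PipelineError(f"no coverage defined for chromosome {chrom}")
        half = window // 2
        lo, hi = center - half, center + half
        total = self._mass_before(chrom, hi)
        if lo > 1:
            total -= self._mass_before(chrom, lo - 1)
        return total / (hi - lo + 1)


def filter_high_coverage_regions(
    calls: Sequence[SVCall],
    coverage: CoverageTrack,
    cfg: SVFilterConfig,
) -> list[SVCall]:
    """Drop calls whose window around the start has mean coverage strictly
    above ``cov_threshold`` (collapsed-repeat pile-ups produce spurious SV
    signal)."""
    return [
        c
        for c in calls
        if coverage.window_mean(c.chrom, c.start, cfg.cov_window) <= cfg.cov_threshold
    ]


def intersect_callsets(
    set_a: Sequence[SVCall],
    set_b: Sequence[SVCall],
    cfg: SVFilterConfig,
) -> list[SVCall]:
    """Calls of set A with at least one lenient equivalent in set B.

    The representative comes from set A; output is ordered by (chrom, start).
    """
    index = _SVIndex(set_b)
    kept = [c for c in set_a if index.has_equivalent(c, cfg)]
    kept.sort(key=lambda c: (c.chrom, c.start))
    return kept


def _cohort_unique(
    per_line: Mapping[str, Sequence[SVCall]], cfg: SVFilterConfig
) -> dict[str, list[SVCall]]:
    """Keep only calls with no lenient equivalent in any other line."""
    indexes = {line: _SVIndex(calls) for line, calls in per_line.items()}
    out: dict[str, list[SVCall]] = {}
    for line, calls in per_line.items():
        others = [idx for other, idx in indexes.items() if other != line]
        out[line] = [
            c for c in calls if not any(idx.has_equivalent(c, cfg) for idx in others)
        ]
    return out


def consensus_sv_pipeline(
    per_line_a: Mapping[str, Sequence[SVCall]],
    per_line_b: Mapping[str, Sequence[SVCall]],
    ancestor_a: Sequence[SVCall],
    ancestor_b: Sequence[SVCall],
    coverage: CoverageTrack,
    cfg: SVFilterConfig,
) -> dict[str, list[SVCall]]:
    """Full consensus cascade over a cohort's two caller outputs.

    Caller-A branch: ancestor subtraction -> hard filters -> high-coverage
    exclusion -> cohort uniqueness.  Caller-B branch: ancestor subtraction ->
    cohort uniqueness (no hard/coverage filters, matching the asymmetric
    treatment of a split-read caller used as confirmation).  Final calls per
    line are the A-branch calls with an equivalent B-branch call.
    """
    if set(per_line_a) != set(per_line_b):
        raise PipelineError("caller A and B cover different line sets")

    branch_a = {
        line: filter_high_coverage_regions(
            apply_sv_hard_filters(
                subtract_callset(calls, ancestor_a, cfg), cfg
            ),
            coverage,
            cfg,
        )
        for line, calls in per_line_a.items()
    }
    branch_a = _cohort_unique(branch_a, cfg)

    branch_b = {
        line: subtract_callset(calls, ancestor_b, cfg)
        for line, calls in per_line_b.items()
    }
    branch_b = _cohort_unique(branch_b, cfg)

    return {
        line: intersect_callsets(branch_a[line], branch_b[line], cfg)
        for line in branch_a
    }
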