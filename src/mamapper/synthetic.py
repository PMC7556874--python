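"""Simulators emulating a mutation-accumulation (MA) study design.

Three generators cover the pipeline's inputs:

* ``simulate_ma_cohort`` — an ancestor plus derived MA lines propagated by
  single-individual bottlenecks: background variants shared cohort-wide and
  Poisson numbers of line-private de novo mutations fixed by drift.
* ``simulate_backcross_panel`` — serially backcrossed, selfed lines with
  Poisson crossovers per chromosome, a single causal locus of incomplete
  penetrance, and binomial phenotype replicates.
* ``simulate_sv_callsets`` — two noisy views of a true SV set, mimicking the
  breakpoint jitter and miss rates of complementary SV callers.

Every simulator is a pure function of its config (identical seed gives
byte-identical output when serialized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import (
    ConfigError,
    GenomeModel,
    Interval,
    MarkerGenotype,
    PhenotypeRecord,
    SampleCall,
    SVCall,
    VariantCall,
)

BASES = "ACGT"


@dataclass
class MASimConfig:
    """Study conditions for the MA-cohort simulator.

    Defaults mirror the design this pipeline targets: 250 single-worm
    generations, ~0.4 de novo mutations per genome per generation (about 100
    fixed mutations per line over the experiment), ~58% of short de novo
    events being indels, 20x mean sequencing depth.  ``background_density``
    controls ancestor-vs-reference variants shared by the whole cohort (wild
    ancestors carry many; a reference-strain ancestor carries few).
    ``hotspot`` optionally multiplies the local de novo rate inside one
    region, for planting mutational-hotspot scenarios.
    """

    genome: GenomeModel
    n_lines: int
    generations: int = 250
    mu: float = 0.4
    background_density: float = 100.0
    frac_indel: float = 0.58
    depth_mean: float = 20.0
    het_escape_rate: float = 0.0
    hotspot: Optional[tuple[Interval, float]] = None
    seed: int = 0
    ancestor_name: str = "ancestor"

    def __post_init__(self) -> None:
        if not self.genome.chroms:
            raise ConfigError("genome must declare chromosome lengths")
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        for name, value in [
            ("mu", self.mu),
            ("background_density", self.background_density),
            ("depth_mean", self.depth_mean),
            ("het_escape_rate", self.het_escape_rate),
        ]:
            if value < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_indel <= 1.0:
            raise ConfigError("frac_indel must lie in [0, 1]")

    @property
    def line_names(self) -> list[str]:
        return [f"line{i + 1:02d}" for i in range(self.n_lines)]


def _draw_position(
    rng: np.random.Generator,
    chrom_names: list[str],
    offsets: np.ndarray,
    total: int,
    hotspot: Optional[tuple[Interval, float]],
) -> tuple[str, int]:
    """Draw a genome position uniformly, optionally up-weighting a hotspot."""
    if hotspot is not None:
        region, mult = hotspot
        w_region = mult * region.length
        w_rest = total - region.length
        if rng.random() < w_region / (w_region + w_rest):
            return region.chrom, int(rng.integers(region.start, region.end + 1))
        # fall through: uniform over the rest by rejection
        while True:
            g = int(rng.integers(1, total + 1))
            i = int(np.searchsorted(offsets, g, side="left"))
            chrom, pos = chrom_names[i - 1], g - int(offsets[i - 1])
            if not (chrom == region.chrom and region.contains(pos)):
                return chrom, pos
    g = int(rng.integers(1, total + 1))
    i = int(np.searchsorted(offsets, g, side="left"))
    return chrom_names[i - 1], g - int(offsets[i - 1])


def _make_alleles(
    rng: np.random.Generator, genome: GenomeModel, chrom: str, pos: int, indel: bool
) -> tuple[str, str]:
    if genome.seq is not None and chrom in genome.seq:
        ref_base = genome.seq[chrom][pos - 1]
        if ref_base not in BASES:
            ref_base = "A"
    else:
        ref_base = BASES[rng.integers(0, 4)]
    if not indel:
        alt = BASES[rng.integers(0, 4)]
        while alt == ref_base:
            alt = BASES[rng.integers(0, 4)]
        return ref_base, alt
    size = int(rng.integers(1, 11))  # short indels, 1-10 bp
    tail = "".join(BASES[b] for b in rng.integers(0, 4, size=size))
    if rng.random() < 0.5:
        return ref_base, ref_base + tail  # insertion
    return ref_base + tail, ref_base  # deletion


def simulate_ma_cohort(
    cfg: MASimConfig,
) -> tuple[list[VariantCall], dict[str, set[tuple[str, int, str, str]]]]:
    """Simulate joint genotypes of an ancestor and its derived MA lines.

    Returns the cohort call list (sorted by position) and the truth map:
    line name -> set of planted private de novo keys (chrom, pos, ref, alt).
    Background variants are hom_alt in the ancestor and every line; each line
    receives Poisson(mu x generations) private events, hom_alt except for a
    ``het_escape_rate`` fraction left heterozygous.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = cfg.genome
    chrom_names = sorted(genome.chroms)
    lengths = np.array([genome.chroms[c] for c in chrom_names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    samples = [cfg.ancestor_name] + cfg.line_names
    used: set[tuple[str, int]] = set()

    def fresh_position(hot: Optional[tuple[Interval, float]]) -> tuple[str, int]:
        while True:
            chrom, pos = _draw_position(rng, chrom_names, offsets, total, hot)
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    def depth() -> int:
        return int(rng.poisson(cfg.depth_mean))

    calls: list[VariantCall] = []

    n_background = int(rng.poisson(cfg.background_density * total / 1e6))
    for _ in range(n_background):
        chrom, pos = fresh_position(None)
        ref, alt = _make_alleles(rng, genome, chrom, pos, rng.random() < 0.5)
        calls.append(
            VariantCall(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                qual=float(rng.uniform(100, 2000)),
                samples={s: SampleCall("hom_alt", depth()) for s in samples},
            )
        )

    truth: dict[str, set[tuple[str, int, str, str]]] = {}
    for line in cfg.line_names:
        truth[line] = set()
        n_denovo = int(rng.poisson(cfg.mu * cfg.generations))
        for _ in range(n_denovo):
            chrom, pos = fresh_position(cfg.hotspot)
            ref, alt = _make_alleles(
                rng, genome, chrom, pos, rng.random() < cfg.frac_indel
            )
            gt = "het" if rng.random() < cfg.het_escape_rate else "hom_alt"
            sample_calls = {
                s: SampleCall(gt if s == line else "hom_ref", depth())
                for s in samples
            }
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    qual=float(rng.uniform(100, 2000)),
                    samples=sample_calls,
                )
            )
            if gt == "hom_alt":
                truth[line].add((chrom, pos, ref, alt))

    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls, truth


# ---------------------------------------------------------------------------
# Backcross panel
# ---------------------------------------------------------------------------

@dataclass
class BackcrossSimConfig:
    """Study conditions for a backcross mapping panel.

    A carrier of the causal mutation is crossed ``n_backcross`` times to the
    ancestor (the carrier chromosome is propagated through each round, as in
    a mapping scheme that follows the mutant phenotype), then each line is
    founded by selfing the final hybrid for ``selfing_generations``
    single-hermaphrodite generations.  ``f_anc``/``f_MA`` are the P3.p
    division probabilities of the ancestral vs homozygous-MA causal genotype
    (the causal allele acts recessively here).  ``crossover_rate`` is the
    mean number of crossovers per chromosome per meiosis (default 1.0,
    approximating one obligate chiasma).
    """

    genome: GenomeModel
    markers: list[tuple[str, str, int]]  # (marker id, chrom, pos)
    causal: tuple[str, int]
    n_backcross: int
    n_lines: int
    f_anc: float
    f_MA: float
    n_scored_per_rep: int = 50
    n_reps: int = 2
    selfing_generations: int = 5
    crossover_rate: float = 1.0
    f2_selection: str = "none"  # or "carrier": retain only F2s carrying the MA allele
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.n_backcross < 1:
            raise ConfigError("n_backcross must be >= 1")
        if not (0.0 <= self.f_anc <= 1.0 and 0.0 <= self.f_MA <= 1.0):
            raise ConfigError("penetrances must lie in [0, 1]")
        if self.n_scored_per_rep < 1:
            raise ConfigError("n_scored_per_rep must be >= 1")
        if self.f2_selection not in ("none", "carrier"):
            raise ConfigError("f2_selection must be 'none' or 'carrier'")
        chrom_sizes = self.genome.chroms
        for mid, chrom, pos in self.markers:
            if chrom not in chrom_sizes or not 1 <= pos <= chrom_sizes[chrom]:
                raise ConfigError(f"marker {mid} at {chrom}:{pos} off the genome")
        cchrom, cpos = self.causal
        if cchrom not in chrom_sizes or not 1 <= cpos <= chrom_sizes[cchrom]:
            raise ConfigError(f"causal locus {cchrom}:{cpos} off the genome")


class _Individual:
    """Diploid genotype tracked only at the marker + causal loci.

    Haplotypes are boolean arrays per chromosome (True = MA allele), with
    linkage realized through shared crossover draws per meiosis.
    """

    __slots__ = ("haps",)

    def __init__(self, haps: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.haps = haps


def _gamete(
    ind: _Individual,
    loci: dict[str, np.ndarray],
    chrom_sizes: dict[str, int],
    crossover_rate: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom, positions in loci.items():
        h0, h1 = ind.haps[chrom]
        n_co = rng.poisson(crossover_rate)
        breaks = np.sort(rng.uniform(0, chrom_sizes[chrom], size=n_co))
        start = int(rng.integers(0, 2))
        seg = np.searchsorted(breaks, positions)
        choice = (start + seg) % 2
        out[chrom] = np.where(choice == 0, h0, h1)
    return out


def simulate_backcross_panel(
    cfg: BackcrossSimConfig,
    ancestor_name: str = "ancestor",
    ma_parent_name: str = "MA_parent",
) -> tuple[list[MarkerGenotype], list[PhenotypeRecord], dict]:
    """Simulate genotypes and phenotypes of a backcross mapping panel.

    Returns marker genotypes for every line, phenotype records for the
    ancestor, the MA parent and every line, and a truth dict with the causal
    position and each line's causal genotype.
    """
    # hierarchical streams: the backcross phase, each line's selfing chain
    # and each strain's phenotype draws get independent generators derived
    # from cfg.seed, so replicates are comparable across n_backcross levels
    # (common random numbers in the selfing/phenotype phases)
    rng = np.random.default_rng([cfg.seed, 0])
    chrom_sizes = cfg.genome.chroms
    cchrom, cpos = cfg.causal

    # per-chromosome sorted loci: markers plus the causal position
    loci: dict[str, np.ndarray] = {}
    marker_at: dict[str, list[tuple[str, int]]] = {}
    for chrom in sorted(chrom_sizes):
        pos_list = sorted(
            {pos for _, c, pos in cfg.markers if c == chrom}
            | ({cpos} if chrom == cchrom else set())
        )
        loci[chrom] = np.array(pos_list, dtype=np.int64)
    for mid, chrom, pos in cfg.markers:
        marker_at.setdefault(chrom, []).append((mid, pos))
    causal_idx = int(np.searchsorted(loci[cchrom], cpos))

    def all_ma() -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            c: (np.ones(len(p), bool), np.ones(len(p), bool)) for c, p in loci.items()
        }

    def anc_gamete() -> dict[str, np.ndarray]:
        return {c: np.zeros(len(p), bool) for c, p in loci.items()}

    def carrier_gamete(ind: _Individual) -> dict[str, np.ndarray]:
        # gamete conditioned on carrying the MA allele at the causal locus
        for _ in range(10_000):
            g = _gamete(ind, loci, chrom_sizes, cfg.crossover_rate, rng)
            if g[cchrom][causal_idx]:
                return g
        raise ConfigError("carrier gamete rejection sampling failed")

    # serial backcrosses: the causal-carrying chromosome is followed through
    carrier = _Individual(all_ma())
    for _ in range(cfg.n_backcross):
        child_haps = {}
        gm = carrier_gamete(carrier)
        ga = anc_gamete()
        for chrom in loci:
            child_haps[chrom] = (gm[chrom], ga[chrom])
        carrier = _Individual(child_haps)
    hybrid = carrier  # heterozygous at the causal locus

    lines = [f"BC{cfg.n_backcross}x_line{i + 1:02d}" for i in range(cfg.n_lines)]
    genotypes: list[MarkerGenotype] = []
    phenotypes: list[PhenotypeRecord] = []
    causal_gt: dict[str, str] = {}

    for line_idx, line in enumerate(lines):
        line_rng = np.random.default_rng([cfg.seed, 1, line_idx])
        while True:
            ind = hybrid
            for gen in range(cfg.selfing_generations):
                g1 = _gamete(ind, loci, chrom_sizes, cfg.crossover_rate, line_rng)
                g2 = _gamete(ind, loci, chrom_sizes, cfg.crossover_rate, line_rng)
                ind = _Individual({c: (g1[c], g2[c]) for c in loci})
                if gen == 0 and cfg.f2_selection == "carrier":
                    h0, h1 = ind.haps[cchrom]
                    if not (h0[causal_idx] or h1[causal_idx]):
                        break  # non-carrier F2 discarded; restart this line
            else:
                break

        for chrom, pairs in marker_at.items():
            h0, h1 = ind.haps[chrom]
            for mid, pos in sorted(pairs, key=lambda t: t[1]):
                i = int(np.searchsorted(loci[chrom], pos))
                n_ma = int(h0[i]) + int(h1[i])
                allele = ("ancestral", "het", "MA")[n_ma]
                genotypes.append(MarkerGenotype(line, mid, chrom, pos, allele))

        h0, h1 = ind.haps[cchrom]
        n_ma = int(h0[causal_idx]) + int(h1[causal_idx])
        causal_gt[line] = ("ancestral", "het", "MA")[n_ma]
        freq = cfg.f_MA if n_ma == 2 else cfg.f_anc
        pheno_seed = int(
            np.random.default_rng([cfg.seed, 2, line_idx]).integers(0, 2**31)
        )
        phenotypes.extend(
            simulate_phenotype_counts(
                freq, cfg.n_scored_per_rep, cfg.n_reps, seed=pheno_seed, strain=line
            )
        )

    for k, (strain, freq) in enumerate(
        [(ancestor_name, cfg.f_anc), (ma_parent_name, cfg.f_MA)]
    ):
        pheno_seed = int(np.random.default_rng([cfg.seed, 3, k]).integers(0, 2**31))
        phenotypes.extend(
            simulate_phenotype_counts(
                freq, cfg.n_scored_per_rep, cfg.n_reps, seed=pheno_seed, strain=strain
            )
        )

    truth = {"causal": cfg.causal, "causal_genotype": causal_gt, "lines": lines}
    return genotypes, phenotypes, truth


def simulate_phenotype_counts(
    freq: float,
    n_scored: int,
    n_reps: int,
    seed: int,
    strain: str = "strain",
) -> list[PhenotypeRecord]:
    """Draw ``n_reps`` independent Binomial(n_scored, freq) scoring replicates."""
    if not 0.0 <= freq <= 1.0:
        raise ConfigError("freq must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return [
        PhenotypeRecord(
            strain=strain,
            replicate=f"r{i + 1}",
            n_divided=int(rng.binomial(n_scored, freq)),
            n_scored=n_scored,
        )
        for i in range(n_reps)
    ]


def simulate_gene_models(
    n_genes: int,
    seed: int,
    chrom: str = "chrI",
    median_length: int = 2_000,
    sigma: float = 1.2,
    intergenic_mean: int = 1_000,
) -> list:
    """Generate gene models with a log-normal length distribution.

    Gene lengths in nematode genomes are heavy-tailed (a few genes are two
    orders of magnitude longer than the median); a log-normal with
    ``sigma`` ~ 1.2 around a ~2 kb median reproduces that shape.  Each gene
    gets two exons covering roughly half its span.
    """
    from .model import Gene, Interval

    rng = np.random.default_rng(seed)
    genes = []
    pos = 1_000
    lengths = np.exp(rng.normal(np.log(median_length), sigma, size=n_genes))
    lengths = np.clip(lengths, 200, 200_000).astype(int)
    for i, length in enumerate(lengths):
        start = pos
        end = start + int(length) - 1
        pos = end + 1 + int(rng.integers(200, 2 * intergenic_mean))
        exon1_end = start + max(50, int(length) // 4)
        exon2_start = min(end - 1, exon1_end + max(2, int(length) // 4))
        exons = [Interval(chrom, start, exon1_end)]
        if exon2_start > exon1_end + 1:
            exons.append(Interval(chrom, exon2_start, end))
        genes.append(Gene(f"g{i:05d}", chrom, start, end, exons=exons))
    return genes


# ---------------------------------------------------------------------------
# SV call sets
# ---------------------------------------------------------------------------

def _jitter_sv(
    sv: SVCall, jitter_sd: float, caller: str, rng: np.random.Generator
) -> SVCall:
    start = max(1, sv.start + int(round(rng.normal(0, jitter_sd))))
    if jitter_sd > 0:
        svlen = max(1, int(round(sv.svlen * rng.uniform(0.8, 1.2))))
    else:
        svlen = sv.svlen
    if sv.svtype == "DEL":
        end = start + svlen - 1
    else:
        end = max(start, sv.end + int(round(rng.normal(0, jitter_sd))))
    return SVCall(
        chrom=sv.chrom,
        start=start,
        end=end,
        svtype=sv.svtype,
        svlen=svlen,
        qual=sv.qual,
        dp=sv.dp,
        caller=caller,
    )


def simulate_sv_callsets(
    truth_svs: Sequence[SVCall],
    jitter_sd: float,
    fp_rate: float,
    fn_rate_per_caller: float | tuple[float, float],
    seed: int,
    genome: Optional[GenomeModel] = None,
) -> tuple[list[SVCall], list[SVCall]]:
    """Produce two noisy caller views (A, B) of a true SV set.

    Each caller reports each true SV with probability 1 - fn_rate, with
    breakpoints perturbed by rounded Normal(0, jitter_sd) and length by up to
    +/-20%.  False positives of random type and size are added at
    ``fp_rate`` expected calls per true SV.
    """
    if jitter_sd < 0:
        raise ConfigError("jitter_sd must be >= 0")
    if isinstance(fn_rate_per_caller, (int, float)):
        fn_rates = (float(fn_rate_per_caller), float(fn_rate_per_caller))
    else:
        fn_rates = (float(fn_rate_per_caller[0]), float(fn_rate_per_caller[1]))
    rng = np.random.default_rng(seed)
    chroms = (
        genome.chroms
        if genome is not None
        else {sv.chrom: max(sv.end for sv in truth_svs) + 10_000 for sv in truth_svs}
    ) or {"chrI": 1_000_000}

    callsets: list[list[SVCall]] = []
    for caller, fn in zip(("callerA", "callerB"), fn_rates):
        calls: list[SVCall] = []
        for sv in truth_svs:
            if rng.random() >= fn:
                calls.append(_jitter_sv(sv, jitter_sd, caller, rng))
        n_fp = int(rng.poisson(fp_rate * max(len(truth_svs), 1)))
        chrom_names = sorted(chroms)
        for _ in range(n_fp):
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            svtype = ("DEL", "INS", "DUP", "INV", "ITX")[rng.integers(0, 5)]
            svlen = int(rng.integers(50, 50_000))
            start = int(rng.integers(1, max(2, chroms[chrom] - svlen)))
            end = start + svlen - 1 if svtype == "DEL" else start + int(rng.integers(0, svlen))
            calls.append(
                SVCall(
                    chrom=chrom,
                    start=start,
                    end=max(start, end),
                    svtype=svtype,
                    svlen=svlen,
                    qual=float(rng.uniform(10, 300)),
                    dp=int(rng.poisson(20)),
                    caller=caller,
                )
            )
        calls.sort(key=lambda c: (c.chrom, c.start))
        callsets.append(calls)
    return callsets[0], callsets[1]
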