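"""Sequence-context operations against brute-force oracles, plus the
repeat-enrichment and length-correlation statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from mamapper.context import (
    annotate_mutations,
    count_hits_per_gene,
    distance_to_repeats,
    gc_content_window,
    length_hit_correlation,
    recurrence_distance,
    repeat_enrichment_test,
    substitution_class,
    triplet_context,
)
from mamapper.model import (
    Gene,
    GenomeModel,
    Interval,
    PipelineError,
    ValidationError,
    VariantCall,
)


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("T", "G", "transversion"),  # the kind of change seen at a
            ("T", "C", "transition"),    # Wnt-inhibitor vs kinase locus
            ("A", "G", "transition"),
            ("C", "T", "transition"),
            ("A", "C", "transversion"),
            ("G", "C", "transversion"),
        ],
    )
    def test_classification(self, ref, alt, expected):
        sub, label = substitution_class(ref, alt)
        assert sub == expected
        assert label == f"{ref}-to-{alt}"

    def test_identical_bases_rejected(self):
        with pytest.raises(ValidationError):
            substitution_class("A", "A")


class TestTripletContext:
    def test_known_motifs_on_embedded_sequence(self):
        # the two causal substitutions' motifs, embedded in a fixture
        seq = "GGGGATTGGGGGAGTGG"
        genome = GenomeModel(chroms={"c": len(seq)}, seq={"c": seq})
        assert triplet_context(genome, "c", 7) == "ATT"
        assert triplet_context(genome, "c", 15) == "AGT"

    def test_homopolymer(self):
        genome = GenomeModel(chroms={"c": 5}, seq={"c": "AAAAA"})
        assert triplet_context(genome, "c", 3) == "AAA"

    def test_start_padding_with_n(self):
        genome = GenomeModel(chroms={"c": 5}, seq={"c": "ACGTA"})
        assert triplet_context(genome, "c", 1) == "NNA"
        assert triplet_context(genome, "c", 2) == "NAC"

    def test_matches_string_slicing_on_random_positions(self, seq_genome):
        rng = np.random.default_rng(1)
        seq = seq_genome.seq["chrI"]
        for pos in rng.integers(3, len(seq) + 1, size=1000):
            pos = int(pos)
            assert triplet_context(seq_genome, "chrI", pos) == seq[pos - 3 : pos]


class TestGCWindow:
    def test_pure_at_and_gc(self):
        genome = GenomeModel(
            chroms={"a": 100, "g": 100},
            seq={"a": "AT" * 50, "g": "GC" * 50},
        )
        assert gc_content_window(genome, "a", 50) == 0.0
        assert gc_content_window(genome, "g", 50) == 100.0

    def test_matches_brute_force_on_random_windows(self, seq_genome):
        rng = np.random.default_rng(2)
        seq = seq_genome.seq["chrI"]
        for pos in rng.integers(1, len(seq) + 1, size=1000):
            pos = int(pos)
            lo = max(1, pos - 24)
            hi = min(len(seq), pos + 25)
            window = seq[lo - 1 : hi]
            brute = 100.0 * sum(b in "GC" for b in window) / len(window)
            assert gc_content_window(seq_genome, "chrI", pos) == pytest.approx(brute)

    def test_invariant_under_reverse_complement(self, seq_genome):
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = seq_genome.seq["chrI"]
        rc = "".join(comp[b] for b in reversed(seq))
        rc_genome = GenomeModel(chroms={"chrI": len(rc)}, seq={"chrI": rc})
        rng = np.random.default_rng(3)
        for pos in rng.integers(30, len(seq) - 30, size=200):
            pos = int(pos)
            mirror = len(seq) - pos + 1
            # the even window is asymmetric (24 left, 25 right), so compare
            # with the mirror position's complementary window
            a = gc_content_window(seq_genome, "chrI", pos, window=51)
            b = gc_content_window(rc_genome, "chrI", mirror, window=51)
            assert a == pytest.approx(b)


class TestRepeatDistances:
    REPEATS = [Interval("chrI", 100, 200), Interval("chrI", 500, 600)]

    def test_inside_repeat_is_zero_zero(self):
        rd = distance_to_repeats(150, self.REPEATS)
        assert (rd.d5, rd.d3, rd.in_repeat) == (0, 0, True)

    def test_between_repeats(self):
        rd = distance_to_repeats(350, self.REPEATS)
        assert (rd.d5, rd.d3) == (150, 150)
        assert not rd.in_repeat and not rd.open5 and not rd.open3

    def test_open_flanks_report_chromosome_distance(self):
        rd = distance_to_repeats(50, self.REPEATS, chrom_length=1000)
        assert rd.open5 and rd.d5 == 49
        rd = distance_to_repeats(700, self.REPEATS, chrom_length=1000)
        assert rd.open3 and rd.d3 == 300

    def test_no_repeats_raises(self):
        with pytest.raises(PipelineError):
            distance_to_repeats(10, [])

    def test_matches_brute_force_on_random_loci(self):
        rng = np.random.default_rng(5)
        # random non-overlapping repeats, including some adjacent ones
        bounds = np.sort(rng.choice(np.arange(1, 100_000), 400, replace=False))
        repeats = [
            Interval("chrI", int(bounds[i]), int(bounds[i + 1]))
            for i in range(0, 400, 2)
        ]
        for pos in rng.integers(1, 100_000, size=1000):
            pos = int(pos)
            got = distance_to_repeats(pos, repeats, chrom_length=100_000)
            inside = any(r.start <= pos <= r.end for r in repeats)
            assert got.in_repeat == inside
            if inside:
                assert (got.d5, got.d3) == (0, 0)
                continue
            left = [pos - r.end for r in repeats if r.end < pos]
            right = [r.start - pos for r in repeats if r.start > pos]
            assert got.d5 == (min(left) if left else pos - 1)
            assert got.d3 == (min(right) if right else 100_000 - pos)


class TestRepeatEnrichment:
    def test_published_scale_example_is_overwhelming(self):
        # 42% of 3469 mutations in repeats covering 20% of the genome
        chi2, p = repeat_enrichment_test(1457, 3469, 0.20)
        assert p < 2.2e-16
        assert chi2 > 900

    def test_exact_expectation_gives_null(self):
        chi2, p = repeat_enrichment_test(20, 100, 0.20)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_direction_agrees_with_binomial_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(30, 300))
            f = float(rng.uniform(0.1, 0.6))
            x = int(rng.integers(0, n + 1))
            _, p_chi = repeat_enrichment_test(x, n, f)
            p_binom = stats.binomtest(x, n, f).pvalue
            # chi-square approximation: same order of magnitude and
            # identical direction of evidence
            if p_binom < 0.01:
                assert p_chi < 0.05
            if p_binom > 0.5:
                assert p_chi > 0.1

    def test_small_expected_cell_warns(self):
        with pytest.warns(UserWarning):
            repeat_enrichment_test(1, 3, 0.1)


from mamapper.synthetic import simulate_gene_models


def _random_genes(seed, n):
    return simulate_gene_models(n, seed=seed)


class TestLengthHitCorrelation:
    def test_proportional_hits_give_r_one(self):
        genes = [
            Gene("a", "chrI", 1, 1000, [Interval("chrI", 1, 1000)]),
            Gene("b", "chrI", 2000, 5999, [Interval("chrI", 2000, 5999)]),
            Gene("c", "chrI", 10_000, 17_999, [Interval("chrI", 10_000, 17_999)]),
        ]
        hits = [1, 4, 8]  # exactly proportional to length
        r, _ = length_hit_correlation(genes, hits)
        assert r == pytest.approx(1.0)

    def test_hand_computed_four_gene_table(self):
        genes = [
            Gene(f"g{i}", "chrI", s, e)
            for i, (s, e) in enumerate([(1, 100), (200, 499), (600, 1199), (1300, 2299)])
        ]
        hits = [0, 2, 1, 5]
        lengths = [100, 300, 600, 1000]
        # direct Pearson formula
        lx, hy = np.array(lengths, float), np.array(hits, float)
        expected = float(
            np.sum((lx - lx.mean()) * (hy - hy.mean()))
            / math.sqrt(np.sum((lx - lx.mean()) ** 2) * np.sum((hy - hy.mean()) ** 2))
        )
        r, _ = length_hit_correlation(genes, hits)
        assert r == pytest.approx(expected)

    def test_poisson_hits_proportional_to_length_give_high_r(self):
        """Under a rate-proportional-to-length model with thousands of genes
        the length/hit-count correlation is strong (r >= 0.9)."""
        rng = np.random.default_rng(9)
        genes = _random_genes(9, 2000)
        lengths = np.array([g.gene_length for g in genes], float)
        rates = 4000 * lengths / lengths.sum()
        hits = rng.poisson(rates).tolist()
        r, p = length_hit_correlation(genes, hits)
        assert r >= 0.9
        assert p < 1e-10

    def test_hit_counting_by_containment(self):
        genes = _random_genes(12, 50)
        rng = np.random.default_rng(13)
        positions = [("chrI", int(p)) for p in rng.integers(1, 2_000_000, size=500)]
        hits_gene = count_hits_per_gene(genes, positions, mode="gene")
        hits_exon = count_hits_per_gene(genes, positions, mode="exon")
        for g, hg, he in zip(genes, hits_gene, hits_exon):
            brute_g = sum(1 for c, p in positions if c == g.chrom and g.tx_start <= p <= g.tx_end)
            brute_e = sum(
                1 for c, p in positions
                if c == g.chrom and any(e.start <= p <= e.end for e in g.exons)
            )
            assert (hg, he) == (brute_g, brute_e)
            assert he <= hg

    def test_zero_variance_rejected(self):
        genes = _random_genes(1, 5)
        with pytest.raises(PipelineError):
            length_hit_correlation(genes, [3, 3, 3, 3, 3])


class TestRecurrence:
    def test_exact_and_nearby_distances(self):
        ref = {"chrI": [1_000, 5_000], "chrII": [70_000]}
        assert recurrence_distance("chrI", 1_000, ref) == 0
        assert recurrence_distance("chrI", 9_000, ref) == 4_000
        assert recurrence_distance("chrIII", 9_000, ref) == math.inf

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        ref = {"chrI": sorted(rng.integers(1, 10_000_000, size=500).tolist())}
        for pos in rng.integers(1, 10_000_000, size=1000):
            pos = int(pos)
            brute = min(abs(p - pos) for p in ref["chrI"])
            assert recurrence_distance("chrI", pos, ref) == brute


class TestAnnotateMutations:
    def test_annotation_table_columns_and_values(self, seq_genome):
        calls = [
            VariantCall("chrI", 1_200, "A", "G"),   # inside repeat 1000-1500
            VariantCall("chrI", 3_000, "A", "AT"),  # indel between repeats
        ]
        df = annotate_mutations(calls, seq_genome)
        assert list(df["sub_class"]) == ["transition", "indel"]
        row0 = df.iloc[0]
        assert row0["in_repeat"] and row0["d5"] == 0 and row0["d3"] == 0
        row1 = df.iloc[1]
        assert row1["d5"] == 3_000 - 1_500 and row1["d3"] == 5_000 - 3_000
        assert 0 <= row1["gc50"] <= 100
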