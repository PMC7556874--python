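"""Shared fixtures: small genomes and cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mamapper.model import GenomeModel, Interval


@pytest.fixture
def small_genome() -> GenomeModel:
    """Three 20-Mbp chromosomes without sequence (coordinate-only analyses)."""
    return GenomeModel(
        chroms={"chrI": 20_000_000, "chrII": 20_000_000, "chrIII": 20_000_000}
    )


@pytest.fixture
def seq_genome() -> GenomeModel:
    """One 10-kbp chromosome with a reproducible random sequence and repeats."""
    rng = np.random.default_rng(77)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=10_000))
    return GenomeModel(
        chroms={"chrI": 10_000},
        seq={"chrI": seq},
        repeats=[Interval("chrI", 1_000, 1_500), Interval("chrI", 5_000, 5_200)],
    )
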