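import numpy as np
import pytest

from cnaprofiler.segio import (
    AUTOSOMES,
    ALL_CHROMS,
    ChromosomeTable,
    GenomicSegment,
    LocusTable,
    SegmentProfile,
)

TOY_CHROM_LEN = 10_000


@pytest.fixture(scope="session")
def genome() -> ChromosomeTable:
    return ChromosomeTable.hg19()


@pytest.fixture(scope="session")
def loci() -> LocusTable:
    return LocusTable.hg19()


@pytest.fixture(scope="session")
def toy_genome() -> ChromosomeTable:
    """A 24 x 10 kb genome small enough for per-base brute-force oracles."""
    return ChromosomeTable(
        lengths={c: TOY_CHROM_LEN for c in ALL_CHROMS}, assembly="hg19"
    )


def make_profile(genome, segments, sample_id="s", **kwargs) -> SegmentProfile:
    """Profile from (chrom, start, end, cn[, loh]) tuples; 1 probe per kb."""
    segs = []
    for row in segments:
        chrom, start, end, cn = row[:4]
        loh = bool(row[4]) if len(row) > 4 else False
        segs.append(
            GenomicSegment(str(chrom), start, end, max(1, (end - start) // 1000),
                           cn, loh)
        )
    return SegmentProfile(sample_id=sample_id, genome=genome,
                          segments=tuple(segs), **kwargs)


def random_toy_profile(rng: np.random.Generator, toy_genome, sample_id="r"):
    """Random aberrant profile on the toy genome (gains, losses, cnLOH)."""
    segs = []
    n = int(rng.integers(0, 8))
    for _ in range(n):
        chrom = str(rng.choice(AUTOSOMES))
        start = int(rng.integers(0, TOY_CHROM_LEN - 100))
        end = int(rng.integers(start + 50, min(TOY_CHROM_LEN, start + 4000)))
        cn, loh = [(3, False), (4, False), (1, False), (0, False), (2, True)][
            int(rng.integers(5))
        ]
        segs.append((chrom, start, end, cn, loh))
    return make_profile(toy_genome, segs, sample_id=sample_id)
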