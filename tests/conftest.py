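import pytest

from hrdscore.genome_model import (
    GenomeSpec,
    Segment,
    SegmentProfile,
    load_genome,
)
from hrdscore.scores import ScoringConfig

MB = 1_000_000


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSpec:
    return load_genome("toy")


@pytest.fixture(scope="session")
def hg19_genome() -> GenomeSpec:
    return load_genome("hg19")


@pytest.fixture(scope="session")
def cfg() -> ScoringConfig:
    return ScoringConfig()


def make_profile(sample_id, *rows, valid=True) -> SegmentProfile:
    """rows: (chrom, start_mb, end_mb, major, minor), coordinates in Mb."""
    segs = [
        Segment(chrom, int(s * MB), int(e * MB), major, minor)
        for chrom, s, e, major, minor in rows
    ]
    return SegmentProfile(sample_id=sample_id, segments=segs, valid=valid)


def flat_profile(sample_id, genome, state=(1, 1)) -> SegmentProfile:
    segs = [
        Segment(c.name, 0, c.length, state[0], state[1])
        for c in genome.chromosomes
    ]
    return SegmentProfile(sample_id=sample_id, segments=segs)
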