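import pytest

from hrdscar import load_genome
from hrdscar.genome import Segment, SegmentProfile


@pytest.fixture(scope="session")
def toy_genome():
    return load_genome("toy")


@pytest.fixture(scope="session")
def grch38():
    return load_genome("GRCh38-autosomes")


def seg(chrom, start_mb, end_mb, major, minor):
    """Shorthand: a segment with Mb coordinates (1-based inclusive bp)."""
    mb = 1_000_000
    return Segment(
        chrom=chrom,
        start=int(start_mb * mb) + 1,
        end=int(end_mb * mb),
        total_cn=major + minor,
        major_cn=major,
        minor_cn=minor,
    )


def profile(*segments, sample_id="t", ploidy=2.0):
    ordered = sorted(segments, key=lambda s: (s.chrom, s.start))
    return SegmentProfile(sample_id=sample_id, ploidy=ploidy, segments=tuple(ordered))
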