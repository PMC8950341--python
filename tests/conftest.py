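from __future__ import annotations

import pysam
import pytest

from refdup.reference_io import Genome
from refdup.simgen import make_random_genome


def sam_records(lengths: dict[str, int], rows: list[str]) -> list[pysam.AlignedSegment]:
    """Build pysam records from raw SAM row strings for unit tests."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": name, "LN": ln} for name, ln in lengths.items()],
        }
    )
    return [pysam.AlignedSegment.fromstring(row, header) for row in rows]


def simple_read(
    name: str,
    contig: str,
    pos: int,
    seq: str,
    mapq: int = 60,
    flag: int = 0,
    cigar: str | None = None,
    lengths: dict[str, int] | None = None,
) -> pysam.AlignedSegment:
    cigar = cigar or f"{len(seq)}M"
    lengths = lengths or {contig: 10_000}
    row = f"{name}\t{flag}\t{contig}\t{pos + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
    return sam_records(lengths, [row])[0]


@pytest.fixture
def tiny_genome() -> Genome:
    return Genome({"a": "ACGTACGT"})


@pytest.fixture
def random_10kb() -> Genome:
    return make_random_genome({"chr1": 10_000}, seed=1)
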