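"""A minimal deterministic seed-and-extend read mapper.

The mapper exists to reproduce one phenomenon faithfully: a read that is
equally consistent with two reference loci cannot be uniquely placed, and
receives mapping quality (MAPQ) 0 — the convention real aligners such as
BWA-MEM use for multimapping reads.  When a duplicated block is present in
the reference, reads sampled from the true locus tie between the two copies,
their MAPQ collapses to 0, and any downstream analysis that filters on MAPQ
goes blind in that region.  Hard-masking one copy removes its seeds, the
ties disappear, and mapping quality recovers.

Alignment is ungapped: candidates are located by exact k-mer seeds taken at
stride k across the read (both strands) and scored by full-length Hamming
distance.  MAPQ is a coarse ladder: 0 for a tie, otherwise
min(60, 20 x (second_best - best)) with a lone candidate treated as
uncontested (60).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .reference_io import Genome
from ._util import revcomp, seq_to_array

__all__ = [
    "ReadAlignment",
    "SeedIndex",
    "index_reference",
    "map_read",
    "map_reads",
    "write_sam",
    "read_fastq",
]


@dataclass(frozen=True)
class ReadAlignment:
    """One read's placement (or non-placement) on the reference."""

    name: str
    contig: str
    pos: int  # 0-based leftmost reference position
    strand: str  # "+" or "-"
    mapq: int
    mismatches: int
    cigar: str
    is_mapped: bool
    seq: str  # as aligned (reverse-complemented for "-" strand)

    @classmethod
    def unmapped(cls, name: str, seq: str) -> "ReadAlignment":
        return cls(name, "*", 0, "+", 0, 0, "*", False, seq)


class SeedIndex:
    """Forward-strand k-mer index over a genome, with cached byte arrays."""

    def __init__(self, genome: Genome, k: int):
        if k < 11:
            raise ValueError(f"k must be >= 11, got {k}")
        self.k = k
        self.genome = genome
        self.contig_order = {name: i for i, name in enumerate(genome)}
        self.arrays = {name: seq_to_array(seq) for name, seq in genome.items()}
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in genome.items():
            add = self.seeds.setdefault
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue  # masked sequence generates no seeds
                add(kmer, []).append((contig, i))


def index_reference(genome: Genome, k: int = 21) -> SeedIndex:
    """Build the seed index used by :func:`map_read`."""
    return SeedIndex(genome, k)


def default_max_mismatches(read_len: int) -> int:
    return int(np.ceil(0.05 * read_len))


def map_read(
    name: str,
    seq: str,
    index: SeedIndex,
    max_mismatches: int | None = None,
    tie_break: str = "lowest",
    rng: np.random.Generator | None = None,
) -> ReadAlignment:
    """Place one read on the reference.

    Candidate positions come from exact seed hits of the read and its
    reverse complement; each candidate is scored by ungapped full-length
    mismatch count.  A unique best placement gets MAPQ
    min(60, 20 x (second_best - best)); a tie for best gets MAPQ 0.  With
    ``tie_break="lowest"`` (default) the tied candidate with the smallest
    (contig order, position) is reported — deterministic; with ``"random"``
    one tied candidate is chosen via ``rng``, emulating the arbitrary
    primary selection of production aligners.
    """
    k = index.k
    length = len(seq)
    if length < k:
        return ReadAlignment.unmapped(name, seq)
    if max_mismatches is None:
        max_mismatches = default_max_mismatches(length)

    candidates: set[tuple[str, int, str]] = set()
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        get = index.seeds.get
        for off in range(0, length - k + 1, k):
            for contig, pos in get(oriented[off : off + k], ()):
                start = pos - off
                if 0 <= start <= len(index.genome[contig]) - length:
                    candidates.add((contig, start, strand))
    if not candidates:
        return ReadAlignment.unmapped(name, seq)

    fwd = seq_to_array(seq)
    rev = seq_to_array(revcomp(seq))
    scored = []
    for contig, start, strand in candidates:
        ref = index.arrays[contig][start : start + length]
        mm = int(np.count_nonzero(ref != (fwd if strand == "+" else rev)))
        scored.append((mm, index.contig_order[contig], start, strand, contig))
    scored.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    best = scored[0][0]
    if best > max_mismatches:
        return ReadAlignment.unmapped(name, seq)
    ties = [t for t in scored if t[0] == best]
    if len(ties) > 1:
        mapq = 0
        if tie_break == "random":
            if rng is None:
                raise ValueError("tie_break='random' requires an rng")
            pick = ties[int(rng.integers(len(ties)))]
        else:
            pick = ties[0]
    else:
        pick = ties[0]
        second = scored[1][0] if len(scored) > 1 else None
        mapq = 60 if second is None else min(60, 20 * (second - best))
    _, _, start, strand, contig = pick
    return ReadAlignment(
        name=name,
        contig=contig,
        pos=start,
        strand=strand,
        mapq=mapq,
        mismatches=best,
        cigar=f"{length}M",
        is_mapped=True,
        seq=seq if strand == "+" else revcomp(seq),
    )


def map_reads(
    reads: Iterable[tuple[str, str]],
    index: SeedIndex,
    max_mismatches: int | None = None,
    tie_break: str = "lowest",
    seed: int | None = None,
) -> list[ReadAlignment]:
    """Map (name, sequence) pairs; see :func:`map_read`."""
    rng = np.random.default_rng(seed) if tie_break == "random" else None
    return [
        map_read(name, seq, index, max_mismatches, tie_break, rng)
        for name, seq in reads
    ]


def write_sam(alignments: Sequence[ReadAlignment], genome: Genome, path) -> None:
    """Write alignments as plain-text SAM with @HD/@SQ headers.

    Mapped reads get flag 0/16 (strand), 1-based POS, CIGAR ``<len>M``;
    unmapped reads get flag 4, POS 0, MAPQ 0, CIGAR ``*``.  The output is
    parseable by pysam and by the depth/pileup stages.
    """
    for aln in alignments:
        if aln.is_mapped and aln.contig not in genome:
            raise ValueError(f"alignment contig {aln.contig!r} not in genome")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln in alignments:
            if aln.is_mapped:
                flag = 16 if aln.strand == "-" else 0
                fh.write(
                    f"{aln.name}\t{flag}\t{aln.contig}\t{aln.pos + 1}\t"
                    f"{aln.mapq}\t{aln.cigar}\t*\t0\t0\t{aln.seq}\t*\t"
                    f"NM:i:{aln.mismatches}\n"
                )
            else:
                fh.write(f"{aln.name}\t4\t*\t0\t0\t*\t*\t0\t0\t{aln.seq}\t*\n")


def read_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper()
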