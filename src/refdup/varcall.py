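"""Threshold-based pileup SNV calling with MAPQ gating.

This caller reproduces the decision logic of a VarScan-style single-sample
run: a variant is emitted at a position when depth, alt-read count, variant
allele frequency (VAF) and strand balance all clear fixed thresholds.  The
defaults mirror the common panel-sequencing parameterization
(min coverage 20, min alt reads 5, min VAF 0.05, strand filter on).

The crucial detail for the duplication failure mode is the MAPQ gate:
reads with mapping quality below ``min_mapq`` (default 1, i.e. MAPQ 0 is
excluded) contribute nothing to the pileup.  Over a duplicated reference
block almost every read is MAPQ 0, the pileup empties out, and real
variants silently fail the depth and alt-count thresholds.

No per-variant significance test is applied; the logic is purely
threshold-based (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pysam

from .errors import CoordinateError
from .reference_io import Genome
from ._util import BASE_CODE, BASES, seq_to_array

__all__ = [
    "CallerParams",
    "PileupColumn",
    "VariantCall",
    "build_pileup",
    "call_variants",
    "write_vcf",
    "read_vcf",
]


@dataclass(frozen=True)
class CallerParams:
    """Calling thresholds (VarScan-style single-sample parameterization)."""

    min_coverage: int = 20
    min_reads2: int = 5
    min_var_freq: float = 0.05
    strand_filter: bool = True
    min_mapq: int = 1
    # maximum share of alt reads allowed on a single strand when the
    # strand filter is active
    max_strand_share: float = 0.9

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_reads2 < 1:
            raise ValueError("min_reads2 must be >= 1")
        if not 0 < self.min_var_freq <= 1:
            raise ValueError("min_var_freq must be in (0, 1]")


@dataclass
class PileupColumn:
    """Per-strand base counts at one reference position.

    ``counts`` has shape (5, 2): rows A,C,G,T,N; columns (+, -) strand.
    """

    contig: str
    pos: int  # 0-based
    ref: str
    counts: np.ndarray = field(default_factory=lambda: np.zeros((5, 2), dtype=np.int64))

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def base_count(self, base: str) -> int:
        return int(self.counts[BASES.index(base)].sum())


@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide variant passing all thresholds."""

    contig: str
    pos: int  # 0-based
    ref: str
    alt: str
    depth: int
    alt_count: int
    vaf: float
    alt_plus: int
    alt_minus: int


def build_pileup(
    alignments: Iterable[pysam.AlignedSegment] | str,
    genome: Genome,
    min_mapq: int = 1,
) -> list[PileupColumn]:
    """Tally aligned read bases per position, by strand, above a MAPQ floor.

    Reads with MAPQ < ``min_mapq`` contribute nothing — this is the gate
    that silences variants inside multimapping-collapse regions.  Deleted
    reference positions contribute no base counts.  Returns columns for
    every position with nonzero depth, sorted by (contig order, position).
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, "r") as fh:
            return build_pileup(list(fh), genome, min_mapq)

    counts = {
        contig: np.zeros((len(seq), 5, 2), dtype=np.int32)
        for contig, seq in genome.items()
    }
    for read in alignments:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < min_mapq
        ):
            continue
        contig = read.reference_name
        if contig not in counts:
            raise CoordinateError(f"read contig {contig!r} not in genome")
        arr = counts[contig]
        strand = 1 if read.is_reverse else 0
        query = seq_to_array(read.query_sequence)
        qpos = rpos = 0
        rstart = read.reference_start
        for op, length in read.cigartuples:
            if op in (0, 7, 8):  # M, =, X: aligned bases
                positions = rstart + rpos + np.arange(length)
                if positions[-1] >= arr.shape[0]:
                    raise CoordinateError(
                        f"read {read.query_name!r} extends past contig end"
                    )
                codes = BASE_CODE[query[qpos : qpos + length]]
                np.add.at(arr, (positions, codes, strand), 1)
                qpos += length
                rpos += length
            elif op in (1, 4):  # I, S consume query only
                qpos += length
            elif op in (2, 3):  # D, N consume reference, no base evidence
                rpos += length

    columns: list[PileupColumn] = []
    for contig, arr in counts.items():
        covered = np.flatnonzero(arr.sum(axis=(1, 2)))
        seq = genome[contig]
        for pos in covered:
            columns.append(
                PileupColumn(contig, int(pos), seq[pos], arr[pos].astype(np.int64))
            )
    return columns


def call_variants(
    pileup: Iterable[PileupColumn], params: CallerParams | None = None
) -> list[VariantCall]:
    """Emit SNV calls from pileup columns under the configured thresholds.

    Per column the alt allele is the non-reference base with the highest
    count (ties broken alphabetically).  A call requires depth >=
    min_coverage, alt reads >= min_reads2, VAF >= min_var_freq and — when
    the strand filter is on — at least one alt read on each strand with no
    strand holding more than ``max_strand_share`` of the alt reads.
    """
    if params is None:
        params = CallerParams()
    calls: list[VariantCall] = []
    for col in pileup:
        depth = col.depth
        if depth < params.min_coverage:
            continue
        best_alt, best_count = None, 0
        for base in "ACGT":
            if base == col.ref:
                continue
            count = col.base_count(base)
            if count > best_count:
                best_alt, best_count = base, count
        if best_alt is None or best_count < params.min_reads2:
            continue
        vaf = best_count / depth
        if vaf < params.min_var_freq:
            continue
        plus = int(col.counts[BASES.index(best_alt), 0])
        minus = int(col.counts[BASES.index(best_alt), 1])
        if params.strand_filter:
            if plus < 1 or minus < 1:
                continue
            if max(plus, minus) / best_count > params.max_strand_share:
                continue
        calls.append(
            VariantCall(
                col.contig, col.pos, col.ref, best_alt,
                depth, best_count, vaf, plus, minus,
            )
        )
    return calls


def write_vcf(calls: Iterable[VariantCall], genome: Genome, path) -> None:
    """Write calls as minimal VCFv4.2 (1-based POS; DP/AD/VAF in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt read count">\n')
        fh.write(
            '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n'
        )
        for contig, length in genome.lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"DP={c.depth};AD={c.alt_count};VAF={c.vaf:.4f}\n"
            )


def read_vcf(path) -> list[VariantCall]:
    """Parse a VCF written by :func:`write_vcf` back into calls."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            depth = int(rec.info["DP"])
            alt_count = int(rec.info["AD"])
            calls.append(
                VariantCall(
                    rec.chrom, rec.pos - 1, rec.ref, rec.alts[0],
                    depth, alt_count, alt_count / depth, 0, 0,
                )
            )
    return calls
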