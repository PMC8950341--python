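"""MAPQ-stratified depth profiling and multimapping-collapse detection.

Coverage of reads with MAPQ > 0 is the diagnostic statistic: over a
duplicated reference block, total depth can look normal while nearly every
read is multimapped (MAPQ 0), so MQ>0 depth collapses toward zero.  This
module computes per-base depth split into an MQ-pass stratum and an MQ0
stratum, flags windows dominated by MQ0 reads, and summarizes MQ-pass depth
over annotated features (e.g. exons).

Depth counts reference-consuming CIGAR operations (M, =, X and D); insertions
and clips do not cover reference positions.  Secondary (0x100),
supplementary (0x800) and duplicate-marked (0x400) records are excluded, as
are unmapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import CoordinateError, SamError
from .reference_io import Feature

__all__ = [
    "DepthProfile",
    "CollapseRegion",
    "FeatureCoverageSummary",
    "depth_profile",
    "depth_profiles",
    "collapse_regions",
    "feature_coverage_summary",
    "lower_median",
    "write_depth_tsv",
    "write_collapse_bed",
    "write_feature_summary_tsv",
]

# CIGAR operation codes that consume reference bases (pysam numeric codes)
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass
class DepthProfile:
    """Per-base depth for one contig, split by mapping-quality stratum."""

    contig: str
    depth_mq_pass: np.ndarray  # reads with MAPQ > min_mapq threshold
    depth_mq0: np.ndarray  # reads at or below the threshold

    @property
    def total(self) -> np.ndarray:
        return self.depth_mq_pass + self.depth_mq0

    def __post_init__(self):
        if self.depth_mq_pass.shape != self.depth_mq0.shape:
            raise ValueError("depth arrays must have identical length")


@dataclass(frozen=True)
class CollapseRegion:
    """A merged run of windows where MQ0 reads dominate the depth."""

    contig: str
    start: int
    end: int
    mean_mq0_fraction: float


@dataclass(frozen=True)
class FeatureCoverageSummary:
    """MQ-pass depth summary over one named interval."""

    name: str
    median_mq_pass_depth: float
    mean_mq_pass_depth: float
    fraction_zero_depth: float


def _keep(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def _ref_spans(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference intervals covered by the read (M/D/=/X; N splits a span)."""
    if read.cigartuples is None:
        raise SamError(f"read {read.query_name!r}: missing CIGAR")
    spans = []
    pos = read.reference_start
    span_start = pos
    for op, length in read.cigartuples:
        if op in _REF_CONSUMING:
            if op == 3:  # N: skipped region, split coverage
                if pos > span_start:
                    spans.append((span_start, pos))
                span_start = pos + length
            pos += length
    if pos > span_start:
        spans.append((span_start, pos))
    return spans


def depth_profile(
    alignments: Iterable[pysam.AlignedSegment] | str,
    contig: str,
    contig_length: int,
    min_mapq: int = 1,
) -> DepthProfile:
    """Per-base depth over ``contig`` split by MAPQ stratum.

    ``alignments`` may be a SAM path or an iterable of pysam records.  Each
    primary mapped non-duplicate read adds 1 to every reference position it
    covers, routed to the MQ-pass stratum when MAPQ >= ``min_mapq``
    (default: MAPQ > 0) and to the MQ0 stratum otherwise.
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, "r") as fh:
            return depth_profile(list(fh), contig, contig_length, min_mapq)
    diff_pass = np.zeros(contig_length + 1, dtype=np.int64)
    diff_mq0 = np.zeros(contig_length + 1, dtype=np.int64)
    for read in alignments:
        if not _keep(read) or read.reference_name != contig:
            continue
        diff = diff_pass if read.mapping_quality >= min_mapq else diff_mq0
        for start, end in _ref_spans(read):
            if end > contig_length:
                raise CoordinateError(
                    f"read {read.query_name!r} extends past contig end "
                    f"({end} > {contig_length})"
                )
            diff[start] += 1
            diff[end] -= 1
    return DepthProfile(
        contig,
        np.cumsum(diff_pass[:-1]),
        np.cumsum(diff_mq0[:-1]),
    )


def depth_profiles(sam_path: str, lengths: dict[str, int], min_mapq: int = 1) -> dict[str, DepthProfile]:
    """Depth profiles for every contig in ``lengths`` from one SAM file."""
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        reads = list(fh)
    return {
        contig: depth_profile(reads, contig, length, min_mapq)
        for contig, length in lengths.items()
    }


def collapse_regions(
    profile: DepthProfile,
    window: int = 500,
    min_mq0_fraction: float = 0.5,
    min_len: int = 1000,
    min_total_depth: int = 10,
) -> list[CollapseRegion]:
    """Regions where multimapped (MQ0) reads dominate coverage.

    Slides a window of ``window`` bp at step window/2; a window qualifies
    when its summed depth is at least ``min_total_depth`` and the MQ0 share
    of that depth is at least ``min_mq0_fraction``.  Qualifying overlapping
    windows are merged; merged regions shorter than ``min_len`` are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(profile.depth_mq0)
    step = max(1, window // 2)
    cum0 = np.concatenate([[0], np.cumsum(profile.depth_mq0)])
    cump = np.concatenate([[0], np.cumsum(profile.depth_mq_pass)])

    qualifying: list[tuple[int, int]] = []
    for start in range(0, max(n - window + 1, 1), step):
        end = min(start + window, n)
        mq0 = cum0[end] - cum0[start]
        total = mq0 + (cump[end] - cump[start])
        if total < min_total_depth:
            continue
        if mq0 / total >= min_mq0_fraction:
            qualifying.append((start, end))

    regions: list[CollapseRegion] = []
    for start, end in _merge(qualifying):
        if end - start < min_len:
            continue
        mq0 = cum0[end] - cum0[start]
        total = mq0 + (cump[end] - cump[start])
        regions.append(
            CollapseRegion(profile.contig, start, end, mq0 / total if total else 0.0)
        )
    return regions


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def lower_median(values: np.ndarray) -> float:
    """Median taking the lower of the two middle values for even counts.

    Depths are integers; this keeps the statistic integral and portable.
    """
    if len(values) == 0:
        raise ValueError("median of empty array")
    ordered = np.sort(np.asarray(values))
    return float(ordered[(len(ordered) - 1) // 2])


def feature_coverage_summary(
    profile: DepthProfile, features: Sequence[Feature]
) -> list[FeatureCoverageSummary]:
    """Per-feature MQ-pass depth statistics (median, mean, zero fraction)."""
    out = []
    n = len(profile.depth_mq_pass)
    for feat in features:
        if feat.contig != profile.contig:
            continue
        if not (0 <= feat.start < feat.end <= n):
            raise CoordinateError(
                f"feature {feat.name!r} [{feat.start}, {feat.end}) out of bounds "
                f"for contig {profile.contig!r} of length {n}"
            )
        depths = profile.depth_mq_pass[feat.start : feat.end]
        out.append(
            FeatureCoverageSummary(
                name=feat.name,
                median_mq_pass_depth=lower_median(depths),
                mean_mq_pass_depth=float(np.mean(depths)),
                fraction_zero_depth=float(np.mean(depths == 0)),
            )
        )
    return out


def write_depth_tsv(profiles: Iterable[DepthProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos0\tmq_pass\tmq0\n")
        for p in profiles:
            for i in range(len(p.depth_mq_pass)):
                fh.write(f"{p.contig}\t{i}\t{p.depth_mq_pass[i]}\t{p.depth_mq0[i]}\n")


def write_collapse_bed(regions: Iterable[CollapseRegion], path) -> None:
    """BED5 with the MQ0 fraction scaled to 0-1000 in the score column."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(1000 * r.mean_mq0_fraction))
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tcollapse\t{score}\n")


def write_feature_summary_tsv(summaries: Iterable[FeatureCoverageSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tmedian_mq_pass\tmean_mq_pass\tfraction_zero\n")
        for s in summaries:
            fh.write(
                f"{s.name}\t{s.median_mq_pass_depth:g}\t"
                f"{s.mean_mq_pass_depth:.3f}\t{s.fraction_zero_depth:.4f}\n"
            )
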