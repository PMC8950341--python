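"""Detection of large near-identical duplicated loci within a reference.

A duplication artifact — for example a BAC clone erroneously incorporated
into an assembly — shows up as two long regions of the reference sharing
very high (here ~99%) sequence identity.  The scanner finds such pairs by
self-comparison: index all forward-strand k-mers, pair up repeated k-mer
occurrences into anchors, chain anchors that lie on a near-constant
alignment diagonal, refine the chain boundaries by ungapped X-drop
extension, and score each candidate region pair by global-alignment percent
identity.

Percent identity is defined as 100 x matching columns / total alignment
columns of a global pairwise alignment, so gap columns count against
identity.  Regions whose combined length exceeds ``exact_limit`` are scored
from the banded edit-distance alignment path instead of the full
dynamic program; both routes use the same column-based identity definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import edlib
import numpy as np
from Bio import Align

from .reference_io import Genome
from ._util import seq_to_array

__all__ = [
    "Anchor",
    "DuplicationPair",
    "build_kmer_index",
    "find_anchors",
    "chain_anchors",
    "alignment_identity",
    "scan_duplications",
    "write_report_tsv",
    "write_mask_bed",
]

# Beyond this combined sequence length the full dynamic program is replaced
# by the banded edit-distance alignment (identical identity definition).
EXACT_ALIGNMENT_LIMIT = 4000


class Anchor(NamedTuple):
    """An exact shared k-mer between two genome positions (forward strand)."""

    contig_a: str
    pos_a: int
    contig_b: str
    pos_b: int
    k: int


class Candidate(NamedTuple):
    """A chained cluster of anchors: two putatively homologous regions."""

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    n_anchors: int


@dataclass(frozen=True)
class DuplicationPair:
    """Two regions of a genome aligned to each other, with percent identity.

    ``region_a`` is the positionally earlier copy (contig order, then
    start); for an assembly artifact the other copy is the usual mask
    target.  Coordinates are 0-based half-open.
    """

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    identity_pct: float
    aligned_length: int


def build_kmer_index(genome: Genome, k: int) -> dict[str, list[tuple[str, int]]]:
    """Map each forward-strand k-mer to its (contig, offset) occurrences.

    k-mers containing N are excluded, which is exactly why hard-masked
    regions are invisible to seed-based mapping.
    """
    if not 1 <= k <= 32:
        raise ValueError(f"k must be in [1, 32], got {k}")
    index: dict[str, list[tuple[str, int]]] = {}
    for contig, seq in genome.items():
        # positions whose k-mer window contains an N are skipped
        n_pos = [i for i, c in enumerate(seq) if c == "N"]
        blocked = np.zeros(max(len(seq) - k + 1, 0), dtype=bool)
        for i in n_pos:
            blocked[max(0, i - k + 1) : i + 1] = True
        for i in range(len(seq) - k + 1):
            if blocked[i]:
                continue
            index.setdefault(seq[i : i + k], []).append((contig, i))
    return index


def find_anchors(
    index: dict[str, list[tuple[str, int]]],
    genome: Genome,
    k: int,
    max_kmer_occurrences: int = 50,
) -> list[Anchor]:
    """Pair up repeated k-mer occurrences into anchors.

    One anchor per ordered pair of distinct positions sharing a k-mer, with
    position order defined by (contig order in the genome, offset).  k-mers
    occurring more than ``max_kmer_occurrences`` times are skipped to
    suppress short tandem/interspersed repeats.
    """
    order = {name: i for i, name in enumerate(genome)}
    anchors: list[Anchor] = []
    for kmer, positions in index.items():
        if len(positions) < 2 or len(positions) > max_kmer_occurrences:
            continue
        pos_sorted = sorted(positions, key=lambda p: (order[p[0]], p[1]))
        for i in range(len(pos_sorted)):
            for j in range(i + 1, len(pos_sorted)):
                (ca, pa), (cb, pb) = pos_sorted[i], pos_sorted[j]
                anchors.append(Anchor(ca, pa, cb, pb, k))
    return anchors


def chain_anchors(
    anchors: list[Anchor],
    max_diagonal_drift: int = 100,
    max_gap: int = 1000,
    min_anchors: int = 5,
) -> list[Candidate]:
    """Merge anchors on near-constant diagonals into candidate region pairs.

    Anchors are grouped by contig pair and sorted by (diagonal, pos_a) where
    diagonal = pos_b - pos_a.  A cluster absorbs the next anchor when its
    diagonal is within ``max_diagonal_drift`` of the cluster's first anchor
    and the pos_a gap to the cluster is at most ``max_gap``.  Clusters with
    fewer than ``min_anchors`` anchors are dropped.  Candidate bounds are
    the min/max anchor start positions with k added to the ends.
    """
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.contig_a, a.contig_b), []).append(a)

    candidates: list[Candidate] = []
    for (ca, cb), group in sorted(by_pair.items()):
        group.sort(key=lambda a: (a.pos_b - a.pos_a, a.pos_a))
        cluster: list[Anchor] = []
        first_diag = 0

        def flush() -> None:
            if len(cluster) >= min_anchors:
                k = cluster[0].k
                sa = min(a.pos_a for a in cluster)
                ea = max(a.pos_a for a in cluster) + k
                sb = min(a.pos_b for a in cluster)
                eb = max(a.pos_b for a in cluster) + k
                candidates.append(Candidate(ca, sa, ea, cb, sb, eb, len(cluster)))

        for a in group:
            diag = a.pos_b - a.pos_a
            if not cluster:
                cluster, first_diag = [a], diag
                continue
            gap = a.pos_a - max(x.pos_a for x in cluster)
            if abs(diag - first_diag) <= max_diagonal_drift and gap <= max_gap:
                cluster.append(a)
            else:
                flush()
                cluster, first_diag = [a], diag
        flush()
    return candidates


def _identity_exact(seq_a: str, seq_b: str) -> tuple[float, int]:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        gap_score=-2,
    )
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    return 100.0 * counts.identities / columns, columns


def _identity_banded(seq_a: str, seq_b: str) -> tuple[float, int]:
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    arr_a, arr_b = seq_to_array(seq_a), seq_to_array(seq_b)
    matches = columns = 0
    ia = ib = 0
    # edlib CIGAR ops: M (aligned columns), I (in query a), D (in target b)
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        columns += n
        if ch == "=" or ch == "M":
            matches += int(np.count_nonzero(arr_a[ia : ia + n] == arr_b[ib : ib + n]))
            ia += n
            ib += n
        elif ch == "X":
            ia += n
            ib += n
        elif ch == "I":
            ia += n
        elif ch == "D":
            ib += n
    return 100.0 * matches / columns, columns


def alignment_identity(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Percent identity and column count of a global alignment of two sequences.

    Identity = 100 x matches / alignment columns; gap columns count against
    identity.  Small problems use the exact dynamic program (match +1,
    mismatch -1, gap -2); larger ones the banded edit-distance path.
    """
    if not seq_a or not seq_b:
        raise ValueError("alignment_identity requires non-empty sequences")
    if len(seq_a) + len(seq_b) <= EXACT_ALIGNMENT_LIMIT:
        return _identity_exact(seq_a, seq_b)
    return _identity_banded(seq_a, seq_b)


# X-drop ungapped extension scoring: generous to the ~1% substitution
# divergence expected inside a duplicated block, hostile to random flanking
# sequence (expected score slope 1 - 3*0.75 < 0).
_XDROP_MATCH = 1
_XDROP_MISMATCH = -2
_XDROP_DROP = 20


def _xdrop_extend(
    seq_a: str, seq_b: str, pos_a: int, pos_b: int, step: int
) -> tuple[int, int]:
    """Extend an ungapped alignment from (pos_a, pos_b) in direction ``step``.

    Returns the (pos_a, pos_b) just past the best-scoring extension point
    (i.e. exclusive bound for step=+1, inclusive start for step=-1).
    """
    best = score = 0
    best_off = 0
    off = 0
    ia, ib = pos_a, pos_b
    while True:
        ia += step
        ib += step
        if not (0 <= ia < len(seq_a) and 0 <= ib < len(seq_b)):
            break
        off += 1
        score += _XDROP_MATCH if seq_a[ia] == seq_b[ib] else _XDROP_MISMATCH
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP_DROP:
            break
    return pos_a + step * best_off, pos_b + step * best_off


def _refine_bounds(genome: Genome, cand: Candidate) -> Candidate:
    """Push candidate boundaries outward to the X-drop optimum."""
    sa, ea = cand.start_a, cand.end_a
    sb, eb = cand.start_b, cand.end_b
    seq_a, seq_b = genome[cand.contig_a], genome[cand.contig_b]
    sa, sb = _xdrop_extend(seq_a, seq_b, sa, sb, -1)
    ea2, eb2 = _xdrop_extend(seq_a, seq_b, ea - 1, eb - 1, +1)
    return cand._replace(start_a=sa, start_b=sb, end_a=ea2 + 1, end_b=eb2 + 1)


def _regions_overlap(c: Candidate) -> bool:
    return c.contig_a == c.contig_b and c.start_a < c.end_b and c.start_b < c.end_a


def scan_duplications(
    genome: Genome,
    k: int = 21,
    min_len: int = 1000,
    min_identity: float = 95.0,
    max_kmer_occurrences: int = 50,
    max_diagonal_drift: int = 100,
    max_gap: int = 1000,
    min_anchors: int = 5,
) -> list[DuplicationPair]:
    """Find near-identical duplicated region pairs within a genome.

    Composition of k-mer indexing, anchor pairing, diagonal chaining,
    boundary refinement and identity scoring.  Pairs shorter than
    ``min_len`` (either region) or below ``min_identity`` are dropped.
    Output is sorted by descending aligned length; each pair is reported
    once with ``region_a`` the positionally earlier region.
    """
    if not 11 <= k <= 32:
        raise ValueError(f"scan k must be in [11, 32], got {k}")
    index = build_kmer_index(genome, k)
    anchors = find_anchors(index, genome, k, max_kmer_occurrences)
    candidates = chain_anchors(anchors, max_diagonal_drift, max_gap, min_anchors)

    order = {name: i for i, name in enumerate(genome)}
    pairs: list[DuplicationPair] = []
    seen: set[tuple] = set()
    for cand in candidates:
        cand = _refine_bounds(genome, cand)
        if _regions_overlap(cand):
            continue
        if cand.end_a - cand.start_a < min_len or cand.end_b - cand.start_b < min_len:
            continue
        key = (cand.contig_a, cand.start_a, cand.end_a,
               cand.contig_b, cand.start_b, cand.end_b)
        if key in seen:
            continue
        seen.add(key)
        seq_a = genome[cand.contig_a][cand.start_a : cand.end_a]
        seq_b = genome[cand.contig_b][cand.start_b : cand.end_b]
        identity, columns = alignment_identity(seq_a, seq_b)
        if identity < min_identity:
            continue
        a = (cand.contig_a, cand.start_a, cand.end_a)
        b = (cand.contig_b, cand.start_b, cand.end_b)
        if (order[b[0]], b[1]) < (order[a[0]], a[1]):
            a, b = b, a
        pairs.append(
            DuplicationPair(*a, *b, identity_pct=identity, aligned_length=columns)
        )
    pairs.sort(key=lambda p: (-p.aligned_length, p.contig_a, p.start_a))
    return pairs


def write_report_tsv(pairs: list[DuplicationPair], path) -> None:
    """TSV report: one duplication pair per row, 0-based half-open coordinates."""
    with open(path, "w") as fh:
        fh.write(
            "contigA\tstartA\tendA\tcontigB\tstartB\tendB\t"
            "identity_pct\taligned_length\n"
        )
        for p in pairs:
            fh.write(
                f"{p.contig_a}\t{p.start_a}\t{p.end_a}\t"
                f"{p.contig_b}\t{p.start_b}\t{p.end_b}\t"
                f"{p.identity_pct:.2f}\t{p.aligned_length}\n"
            )


def write_mask_bed(pairs: list[DuplicationPair], path) -> None:
    """BED of the later-coordinate copy of each pair — the mask target."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.contig_b}\t{p.start_b}\t{p.end_b}\n")
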