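"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code path with the package internals they
verify: full-scan alignment uses numpy sliding windows, masking uses an
explicit position set, and duplication detection uses exhaustive
window-by-window alignment.
"""

from __future__ import annotations

import numpy as np

from refdup.reference_io import Genome
from refdup._util import revcomp


def seq_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def brute_force_best_hits(read: str, genome: Genome):
    """Exhaustive ungapped scan of a read over every position and strand.

    Returns (best_mismatches, [(contig, pos, strand), ...]) over all
    placements achieving the minimum, or (None, []) when the read is longer
    than every contig.
    """
    best = None
    hits: list[tuple[str, int, str]] = []
    length = len(read)
    for contig, seq in genome.items():
        if len(seq) < length:
            continue
        ref = seq_bytes(seq)
        windows = np.lib.stride_tricks.sliding_window_view(ref, length)
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            mm = np.count_nonzero(windows != seq_bytes(oriented), axis=1)
            m = int(mm.min())
            if best is None or m < best:
                best = m
                hits = []
            if m == best:
                hits.extend(
                    (contig, int(p), strand) for p in np.flatnonzero(mm == best)
                )
    return best, hits


def masked_by_position_set(genome: Genome, intervals) -> dict[str, str]:
    """Apply masking one position at a time via an explicit position set."""
    out = {}
    for contig, seq in genome.items():
        masked_positions = set()
        for iv in intervals:
            if iv.contig == contig:
                masked_positions.update(range(iv.start, iv.end))
        out[contig] = "".join(
            "N" if i in masked_positions else c for i, c in enumerate(seq)
        )
    return out


def window_duplicate_exists(
    genome: Genome, identity_fn, window: int = 1000, min_identity: float = 95.0
) -> bool:
    """O(n^2) sliding-window self-comparison duplicate detector.

    Windows of ``window`` bp at stride window/2 across all contigs; a
    duplicate exists when any two non-overlapping windows align at
    >= ``min_identity`` percent identity under the supplied scorer.
    """
    stride = window // 2
    windows = []
    for contig, seq in genome.items():
        for start in range(0, len(seq) - window + 1, stride):
            windows.append((contig, start, seq[start : start + window]))
    for i in range(len(windows)):
        ci, si, wi = windows[i]
        for j in range(i + 1, len(windows)):
            cj, sj, wj = windows[j]
            if ci == cj and abs(si - sj) < window:
                continue  # overlapping placements are not duplications
            identity, _ = identity_fn(wi, wj)
            if identity >= min_identity:
                return True
    return False
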