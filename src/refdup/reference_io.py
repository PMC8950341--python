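"""Reference genome I/O and coordinate-preserving hard-masking.

The remedy for a duplication artifact in a reference assembly is to replace
the erroneously added copy with ``N`` characters.  Hard-masking keeps every
contig name and length unchanged, so all existing annotation, BED files and
variant coordinates remain valid, while short-read aligners no longer seed
any alignment inside the masked interval.

Coordinates are 0-based half-open everywhere inside this package (the BED
convention); conversion to the 1-based inclusive coordinates humans print
happens only at I/O and report boundaries.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Mapping, NamedTuple

from Bio import SeqIO

from .errors import BedError, CoordinateError, FastaError

__all__ = [
    "Genome",
    "MaskInterval",
    "Feature",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_features_bed",
    "mask_fasta",
    "merge_intervals",
]

# Single-base IUPAC codes.  Ambiguity codes other than N are normalized to N
# on load; anything outside this set is rejected with its position.
_IUPAC = set("ACGTNRYSWKMBDHV")
_AMBIGUOUS = set("RYSWKMBDHV")


class Genome(Mapping):
    """An ordered mapping of contig name to uppercase nucleotide string.

    Sequences are normalized on construction: uppercased, with IUPAC
    ambiguity codes collapsed to ``N``.  Contig names must be unique and
    non-empty, sequences non-empty.
    """

    def __init__(self, contigs: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = contigs.items() if isinstance(contigs, Mapping) else contigs
        self._contigs: dict[str, str] = {}
        for name, seq in items:
            if not name:
                raise FastaError("empty contig name")
            if name in self._contigs:
                raise FastaError(f"duplicate contig name: {name!r}")
            if not seq:
                raise FastaError(f"contig {name!r} has an empty sequence")
            self._contigs[name] = _normalize(name, seq)

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return list(self._contigs.items()) == list(other._contigs.items())

    def __repr__(self) -> str:
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self._contigs.items())
        return f"Genome({parts})"

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self._contigs.values())


class MaskInterval(NamedTuple):
    """A BED-style interval designating sequence to replace with N."""

    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


class Feature(NamedTuple):
    """A named BED4 interval (e.g. an exon) for coverage summaries."""

    contig: str
    start: int
    end: int
    name: str


def _normalize(name: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise FastaError(
            f"non-IUPAC character {seq[pos]!r} in contig {name!r} at position {pos}"
        )
    if set(seq) & _AMBIGUOUS:
        seq = "".join("N" if c in _AMBIGUOUS else c for c in seq)
    return seq


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Record order is preserved, multi-line records are concatenated and
    sequences are uppercased.  Raises :class:`FastaError` on an empty file,
    duplicate contig names, or non-IUPAC characters (naming the position).
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaError(f"no records in FASTA file {path}")
    return Genome(records)


def write_fasta(genome: Genome, path, line_width: int = 60) -> None:
    """Write a genome to ``path`` wrapping sequence lines at ``line_width``."""
    if line_width < 1:
        raise ValueError(f"line_width must be positive, got {line_width}")
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width])
                fh.write("\n")


def _parse_bed_lines(path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            yield lineno, fields


def read_bed(path) -> list[MaskInterval]:
    """Read a BED3+ file; columns beyond the third are ignored.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Intervals are returned in file order, validated as 0-based half-open.
    """
    return [
        MaskInterval(f[0], int(f[1]), int(f[2])) for _, f in _parse_bed_lines(path)
    ]


def read_features_bed(path) -> list[Feature]:
    """Read a BED4 file of named features; unnamed rows get ``<contig>:<start>-<end>``."""
    out = []
    for _, f in _parse_bed_lines(path):
        name = f[3] if len(f) >= 4 else f"{f[0]}:{f[1]}-{f[2]}"
        out.append(Feature(f[0], int(f[1]), int(f[2]), name))
    return out


def merge_intervals(intervals: Iterable[MaskInterval]) -> list[MaskInterval]:
    """Union overlapping/adjacent intervals per contig; output sorted."""
    by_contig: dict[str, list[MaskInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    merged: list[MaskInterval] = []
    for contig in by_contig:
        ivs = sorted(by_contig[contig], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(MaskInterval(contig, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(MaskInterval(contig, cur_s, cur_e))
    return merged


def mask_fasta(genome: Genome, intervals: Iterable[MaskInterval]) -> Genome:
    """Replace the bases inside ``intervals`` with ``N``.

    Contig names, order and lengths are preserved exactly — the masked
    genome is coordinate-compatible with the original.  Overlapping
    intervals are unioned.  Raises :class:`CoordinateError` for unknown
    contigs or out-of-bounds coordinates.
    """
    intervals = list(intervals)
    for iv in intervals:
        if iv.contig not in genome:
            raise CoordinateError(f"interval contig {iv.contig!r} not in genome")
        if not (0 <= iv.start < iv.end <= len(genome[iv.contig])):
            raise CoordinateError(
                f"interval [{iv.start}, {iv.end}) out of bounds for contig "
                f"{iv.contig!r} of length {len(genome[iv.contig])}"
            )
    masked = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    for iv in merge_intervals(intervals):
        masked[iv.contig][iv.start : iv.end] = b"N" * (iv.end - iv.start)
    return Genome({name: buf.decode("ascii") for name, buf in masked.items()})


def format_region(contig: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval in the 1-based inclusive style."""
    return f"{contig}:{start + 1}-{end}"


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``contig:start-end`` (1-based inclusive) to 0-based half-open."""
    try:
        contig, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start, end = int(lo) - 1, int(hi)
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}") from exc
    if start < 0 or start >= end:
        raise ValueError(f"invalid region {text!r}")
    return contig, start, end
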