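"""Exception hierarchy.

All data-level failures raise :class:`RefdupError` subclasses so the CLI can
map them to a distinct exit code (2) while usage errors exit 1.
"""


class RefdupError(Exception):
    """Base class for data and format errors raised by refdup."""


class FastaError(RefdupError):
    """Malformed or empty FASTA input."""


class BedError(RefdupError):
    """Malformed BED input."""


class CoordinateError(RefdupError):
    """Interval or position outside the bounds of its contig."""


class SamError(RefdupError):
    """Malformed SAM record (e.g. unparseable CIGAR)."""
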