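"""Small shared helpers: base encoding and reverse complement."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# ASCII code -> 0..4 for A,C,G,T,N (everything else maps to N)
BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_CODE[ord(_b)] = _i
BASES = "ACGTN"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Nucleotide string as a uint8 array of raw ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))
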