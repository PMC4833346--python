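"""Low-level nucleotide sequence helpers shared across modules.

Sequences are plain Python ``str`` over the ACGTN alphabet at module
boundaries; hot paths convert to ``numpy`` ``uint8`` code arrays
(A=0, C=1, G=2, T=3, anything else = 4).
"""

from __future__ import annotations

import numpy as np

_ENCODE = bytes.maketrans(b"ACGTacgt", bytes([0, 1, 2, 3, 0, 1, 2, 3]))
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into uint8 codes; non-ACGT characters map to 4."""
    raw = seq.encode("ascii").translate(_ENCODE)
    arr = np.frombuffer(raw, dtype=np.uint8).copy()
    arr[arr > 3] = 4
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def gc_fraction(seq: str) -> float:
    arr = encode(seq)
    non_n = arr < 4
    if not non_n.any():
        return float("nan")
    gc = np.count_nonzero((arr == 1) | (arr == 2))
    return gc / int(non_n.sum())


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length strings (position-wise)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 100.0
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float(np.count_nonzero(xa == xb)) / len(a)
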