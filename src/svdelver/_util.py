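"""Small shared helpers: sequence codecs and interval arithmetic."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

# uint8 base codes used by the simulator and the alignment kernels
A, C, G, T = 0, 1, 2, 3
CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
    _BASE_TO_CODE[_b + 32] = _i  # lower case


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    return _BASE_TO_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return CODE_TO_BASE[codes].tobytes().decode()


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Intersection length divided by the longer of the two intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return inter / max(a_end - a_start, b_end - b_start)
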